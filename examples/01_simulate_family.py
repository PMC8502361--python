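"""Simulate one pregnancy at risk for a recessive disorder.

Builds a 2 Mb SNP panel with a carrier mother and father (one pathogenic
variant each), draws the fetal genome with genetic-map recombination, and
mixes maternal plasma counts at a 13.2% fetal fraction.
"""

import numpy as np

from haplonipt import simdata
from haplonipt.genetic_map import GeneticMap
from haplonipt.simdata import PathogenicSpec

panel, mother, father = simdata.simulate_parental_diplotypes(
    n_snps=300,
    het_rate=0.6,
    pathogenic_spec={"mother": PathogenicSpec(4_975_000, hap=1),
                     "father": PathogenicSpec(5_025_000, hap=1)},
    seed=1,
)
gmap = GeneticMap.uniform(int(panel.positions[0]), int(panel.positions[-1]), cm_per_mb=1.0)
truth = simdata.simulate_fetal_genome(mother, father, panel, gmap, true_ff=0.132, seed=2)
counts = simdata.simulate_plasma_counts(mother, father, truth, panel,
                                        depth_mean=200, seed=3)

print(f"panel: {len(panel)} SNPs on {panel.chrom}, "
      f"{panel.positions[0]:,}-{panel.positions[-1]:,}")
print(f"mother heterozygous at {int(mother.het_mask.sum())} sites, "
      f"father at {int(father.het_mask.sum())}")
print(f"fetus inherited maternal hap {truth.fetal_mat_hap[0]} / "
      f"paternal hap {truth.fetal_pat_hap[0]} at the left panel edge; "
      f"{len(truth.crossovers)} crossover(s) simulated")
print(f"plasma: mean depth {counts.depth.mean():.0f}x, "
      f"true fetal fraction {truth.true_ff:.3f}")
# the haplotype-dosage signal the pipeline exploits: a few reads per SNP
# tilt toward the inherited maternal haplotype
het = np.flatnonzero(mother.het_mask & ~father.het_mask)
print(f"{len(het)} maternal-informative SNPs carry the maternal RHDO signal")
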