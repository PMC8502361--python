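"""Family-level reporting: fetal genotype categories, cohort summaries,
concordance against a truth table, and the end-to-end pipeline driver.

The packaged cohort tables (``haplonipt.data``) transcribe a published
40-family validation cohort of autosomal-recessive NIPD: family genotypes
and fetal fractions, per-parent phase-block statistics, and the per-family
NIPD calls with their invasive-diagnosis ground truth.  They make the
cohort summaries unit-testable without any sequencing data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from . import confidence as conf
from . import informative_snps as isnp
from . import linked_phasing as lp
from . import rhdo_hmm as hmm
from . import simdata
from .genetic_map import GeneticMap
from .types import (
    Category,
    FamilyReport,
    FetalCall,
    GenotypeCategory,
    State,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# packaged cohort tables

def _load_table(name: str) -> pd.DataFrame:
    with resources.files("haplonipt.data").joinpath(name).open() as fh:
        # keep literal "NA" (not applicable) strings intact
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_family_table() -> pd.DataFrame:
    """Cohort clinical table: parental/fetal genotypes, gestational age
    (weeks, e.g. "12+4" = 12 weeks 4 days) and fetal fraction (%)."""
    df = _load_table("table1_families.tsv")
    df["ff_pct"] = df["ff_pct"].astype(float)
    df["ga_weeks"] = df["ga"].map(parse_gestational_age)
    return df


def load_phase_block_table() -> pd.DataFrame:
    """Per-parent anchoring phase block over the target region."""
    df = _load_table("table2_phase_blocks.tsv")
    for c in ("block_start", "block_end", "n_snps"):
        df[c] = df[c].astype(int)
    df["block_size_kb"] = df["block_size_kb"].astype(float)
    return df


def load_nipd_table() -> pd.DataFrame:
    """Per-family NIPD calls, confidence scores and invasive ground truth.
    "N" = normal allele, "NC" = no-call, "NA" = not applicable (parental
    phasing failed)."""
    df = _load_table("table3_nipd.tsv")
    for c in ("n_mat_informative", "n_pat_informative"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def parse_gestational_age(ga: str) -> float:
    """'12+4' -> 12 + 4/7 weeks; plain '18' -> 18.0."""
    if "+" in ga:
        weeks, days = ga.split("+")
        return int(weeks) + int(days) / 7.0
    return float(ga)


# ---------------------------------------------------------------------------
# genotype categories and concordance

def classify_fetal_genotype(mat_call: FetalCall, pat_call: FetalCall) -> GenotypeCategory:
    """Combine the two per-parent allele calls into a fetal category.

    Both pathogenic -> affected; exactly one -> carrier; neither ->
    normal.  One parent no-call -> partial; both -> no-call.
    """
    alleles = (mat_call.allele, pat_call.allele)
    n_nc = sum(a == "NO_CALL" for a in alleles)
    if n_nc == 2:
        return GenotypeCategory.NO_CALL
    if n_nc == 1:
        return GenotypeCategory.PARTIAL
    n_p = sum(a == "P" for a in alleles)
    return {2: GenotypeCategory.AFFECTED, 1: GenotypeCategory.CARRIER, 0: GenotypeCategory.NORMAL}[n_p]


def _allele_from_string(call: str, parent: str) -> FetalCall:
    """Map a table call string to a FetalCall: a variant name -> P,
    "N" -> N, "NC"/"NA" -> NO_CALL."""
    if call in ("NC", "NA"):
        return FetalCall(parent, "NO_CALL", reason="no-call" if call == "NC" else "phasing failed")
    return FetalCall(parent, "N" if call == "N" else "P")


def cohort_reports_from_nipd_table(df: Optional[pd.DataFrame] = None) -> list[FamilyReport]:
    """Turn the packaged NIPD table into FamilyReports with concordance
    against the invasive diagnosis."""
    if df is None:
        df = load_nipd_table()
    fam = load_family_table().set_index("family")
    out = []
    for _, row in df.iterrows():
        mat = _allele_from_string(row["nipd_mat"], "mat")
        pat = _allele_from_string(row["nipd_pat"], "pat")
        cat = classify_fetal_genotype(mat, pat)
        called = mat.allele != "NO_CALL" and pat.allele != "NO_CALL"
        if called:
            concordant = (row["nipd_mat"] == row["invasive_mat"]) and (
                row["nipd_pat"] == row["invasive_pat"]
            )
        else:
            concordant = None
        out.append(
            FamilyReport(
                family_id=row["family"],
                gene=row["gene"],
                mat_call=mat,
                pat_call=pat,
                genotype_category=cat,
                ff=float(fam.loc[row["family"], "ff_pct"]) / 100.0,
                n_mat_informative=int(row["n_mat_informative"]) if pd.notna(row["n_mat_informative"]) else 0,
                n_pat_informative=int(row["n_pat_informative"]) if pd.notna(row["n_pat_informative"]) else 0,
                concordant_with_truth=concordant,
            )
        )
    return out


def concordance_table(reports: list[FamilyReport], truth: Optional[dict[str, tuple[str, str]]] = None) -> dict:
    """Cohort summary counts.

    ``truth`` maps family_id -> (mat allele, pat allele) in P/N coding;
    when omitted, each report's pre-computed ``concordant_with_truth`` flag
    is used.  A family counts as no-call if either parental allele is
    NO_CALL (includes not-applicable parents).
    """
    n_called_both = n_concordant = n_no_call = 0
    categories: dict[str, int] = {c.value: 0 for c in GenotypeCategory}
    excluded = 0
    for r in reports:
        if truth is not None and r.family_id not in truth:
            logger.warning("family %s missing from truth; excluded", r.family_id)
            excluded += 1
            continue
        categories[r.genotype_category.value] += 1
        fully_called = r.mat_call.allele != "NO_CALL" and r.pat_call.allele != "NO_CALL"
        if not fully_called:
            n_no_call += 1
            continue
        n_called_both += 1
        if truth is not None:
            ok = (r.mat_call.allele, r.pat_call.allele) == truth[r.family_id]
        else:
            ok = bool(r.concordant_with_truth)
        if ok:
            n_concordant += 1
    return {
        "n_families": len(reports) - excluded,
        "n_called_both": n_called_both,
        "n_concordant": n_concordant,
        "n_no_call_families": n_no_call,
        "categories": categories,
        "n_excluded": excluded,
    }


# ---------------------------------------------------------------------------
# end-to-end pipeline on one (simulated or file-backed) family

@dataclass
class PipelineConfig:
    """Inputs and knobs for one family analysis.

    With ``simulate=True`` the family is generated by the synthetic-data
    module (known truth); otherwise parental haplotypes and plasma counts
    must be supplied in memory by the caller (see ``io`` for file loading).
    """

    family_id: str = "SIM"
    gene_interval: tuple[int, int] = (4_950_000, 5_050_000)
    simulate: bool = True
    # simulation settings
    n_snps: int = 300
    region_start: int = 4_000_000
    region_length: int = 2_000_000
    het_rate: float = 0.6
    true_ff: float = 0.132
    plasma_depth: float = 200.0
    plasma_error_rate: float = 0.005
    recombination: bool = True
    linked_reads: bool = True  # phase from simulated barcodes vs truth bypass
    molecule_len_mean: int = 100_000
    molecules_per_partition: int = 10
    linked_read_depth: float = 100.0
    linked_read_error: float = 0.001
    # analysis settings
    ff_override: Optional[float] = None
    epsilon: float = 0.005
    cs_replicates: int = conf.DEFAULT_REPLICATES
    cs_threshold: float = conf.DEFAULT_THRESHOLD
    map_function: str = "haldane"
    min_support: int = 2
    min_margin: int = 2
    # drop the father's linked-read observations at his variant site, so
    # no phase block can cover it (emulates a real phasing failure)
    inject_pat_phasing_failure: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    report: FamilyReport
    mat_path: Optional[hmm.HaplotypePath]
    pat_path: Optional[hmm.HaplotypePath]
    truth: Optional[simdata.SimTruth]
    ff_estimate: float
    extras: dict = field(default_factory=dict)

    def report_json(self) -> str:
        d = {
            "family_id": self.report.family_id,
            "gene": self.report.gene,
            "mat_call": asdict(self.report.mat_call),
            "pat_call": asdict(self.report.pat_call),
            "genotype_category": self.report.genotype_category.value,
            "ff": round(self.report.ff, 6),
            "n_mat_informative": self.report.n_mat_informative,
            "n_pat_informative": self.report.n_pat_informative,
            "concordant_with_truth": self.report.concordant_with_truth,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Full analysis of one simulated family: phase -> classify -> fetal
    fraction -> Viterbi -> call rules -> confidence score -> report."""
    cfg = config
    if not cfg.simulate:
        raise ValueError("file-backed pipelines are driven via the CLI / io module")
    rng_seed = cfg.seed
    g_start, g_end = cfg.gene_interval

    # pathogenic variants placed just outside the gene's two ends, one per parent
    mat_var = int(g_start + 0.25 * (g_end - g_start))
    pat_var = int(g_start + 0.75 * (g_end - g_start))
    panel, mother, father = simdata.simulate_parental_diplotypes(
        n_snps=cfg.n_snps,
        region_length=cfg.region_length,
        het_rate=cfg.het_rate,
        pathogenic_spec={
            "mother": simdata.PathogenicSpec(mat_var, hap=1),
            "father": simdata.PathogenicSpec(pat_var, hap=1),
        },
        seed=rng_seed,
        region_start=cfg.region_start,
    )
    gmap = GeneticMap.uniform(int(panel.positions[0]), int(panel.positions[-1]))
    truth = simdata.simulate_fetal_genome(
        mother, father, panel, gmap,
        recombination=cfg.recombination, true_ff=cfg.true_ff, seed=rng_seed + 1,
        map_function=cfg.map_function,
    )
    counts = simdata.simulate_plasma_counts(
        mother, father, truth, panel,
        depth_mean=cfg.plasma_depth, error_rate=cfg.plasma_error_rate, seed=rng_seed + 2,
    )

    # --- phasing: from simulated barcoded linked reads, or the truth bypass
    if cfg.linked_reads:
        mat_obs = simdata.simulate_linked_reads(
            mother, panel, cfg.molecule_len_mean, cfg.molecules_per_partition,
            cfg.linked_read_depth, cfg.linked_read_error, seed=rng_seed + 3,
        )
        pat_obs = simdata.simulate_linked_reads(
            father, panel, cfg.molecule_len_mean, cfg.molecules_per_partition,
            cfg.linked_read_depth, cfg.linked_read_error, seed=rng_seed + 4,
        )
        if cfg.inject_pat_phasing_failure:
            keep = pat_obs.snp_index != panel.index_of(pat_var)
            pat_obs = simdata.BarcodeObservationTable(
                pat_obs.barcode[keep], pat_obs.snp_index[keep],
                pat_obs.allele[keep],
                None if pat_obs.molecule_id is None else pat_obs.molecule_id[keep])
        mat_pair, mat_blocks = lp.phase_parent(
            mat_obs, mother, panel, mat_var, "mother", cfg.min_support, cfg.min_margin)
        pat_pair, pat_blocks = lp.phase_parent(
            pat_obs, father, panel, pat_var, "father", cfg.min_support, cfg.min_margin)
        # keep P = the simulated pathogenic haplotype for truth comparison:
        # anchoring already guarantees this (P carries the variant allele)
        extras = {
            "mat_block_stats": lp.phase_block_stats(mat_blocks, cfg.gene_interval),
            "pat_block_stats": lp.phase_block_stats(pat_blocks, cfg.gene_interval),
        }
    else:
        mat_pair = lp.haplotype_pair_from_diplotype(mother, "mother")
        pat_pair = lp.haplotype_pair_from_diplotype(father, "father")
        extras = {}

    informative = isnp.classify_informative_snps(mother, father)
    # fetal fraction needs only the genotype configuration, not phasing:
    # estimate it before SNPs outside covered blocks are demoted
    if cfg.ff_override is not None:
        ff = cfg.ff_override
    else:
        ff = isnp.estimate_fetal_fraction(counts, mother, father, informative)
    informative = isnp.annotate_with_haplotypes(informative, mother, father, mat_pair, pat_pair)

    idx, p_counts, n_counts, _ = isnp.extract_haplotype_counts(counts, informative)
    by_index = {s.snp_index: s for s in informative}
    mother_hom = mother.hap1  # valid where mother is hom

    calls: dict[str, FetalCall] = {}
    paths: dict[str, Optional[hmm.HaplotypePath]] = {"mat": None, "pat": None}
    n_info = {"mat": 0, "pat": 0}
    for parent, pair in (("mat", mat_pair), ("pat", pat_pair)):
        if not pair.covered:
            calls[parent] = FetalCall(parent, "NO_CALL", reason="phasing failed")
            continue
        sel, fP, fN = hmm.expected_fraction_arrays(
            informative, mother_hom, ff, parent, cfg.epsilon)
        n_info[parent] = len(sel)
        if len(sel) == 0:
            calls[parent] = FetalCall(parent, "NO_CALL", reason="no informative SNPs")
            continue
        pos_in_idx = {int(i): k for k, i in enumerate(idx)}
        take = np.array([pos_in_idx[int(i)] for i in sel])
        positions = panel.positions[sel]
        path = hmm.viterbi_decode(
            positions, p_counts[take], n_counts[take], fP, fN, gmap, parent, cfg.map_function)
        paths[parent] = path
        call = hmm.call_fetal_allele(path, cfg.gene_interval)
        if call.allele != "NO_CALL":
            cs = conf.confidence_score(
                len(sel), (p_counts[take] + n_counts[take]), ff, call.allele,
                positions, fP, fN, gmap, cfg.gene_interval, parent,
                cfg.cs_replicates, cfg.cs_threshold, seed=rng_seed + 10,
                map_function=cfg.map_function,
            )
            call = conf.attach_confidence(call, cs)
        calls[parent] = call

    category = classify_fetal_genotype(calls["mat"], calls["pat"])

    concordant = None
    if truth is not None:
        true_alleles = _truth_calls(truth, mother, father, panel, cfg.gene_interval)
        concordant = _calls_concordant(calls, true_alleles)

    report = FamilyReport(
        family_id=cfg.family_id,
        gene="SIMGENE",
        mat_call=calls["mat"],
        pat_call=calls["pat"],
        genotype_category=category,
        ff=ff,
        n_mat_informative=n_info["mat"],
        n_pat_informative=n_info["pat"],
        concordant_with_truth=concordant,
    )
    return PipelineResult(report, paths["mat"], paths["pat"], truth, ff, extras)


def _truth_calls(
    truth: simdata.SimTruth,
    mother, father, panel,
    gene_interval: tuple[int, int],
) -> dict[str, str]:
    """True P/N inheritance per parent at the pathogenic sites (state of
    the inherited haplotype inside the gene; assumes no crossover between
    a parent's pathogenic site and the gene interval, which holds for the
    default simulation geometry where the variants sit inside the gene)."""
    out = {}
    for parent, dip, hap_vec in (("mat", mother, truth.fetal_mat_hap), ("pat", father, truth.fetal_pat_hap)):
        vi = [i for i in panel.pathogenic_indices if dip.is_het(i) and dip.pathogenic_hap is not None]
        # the parent's own variant site: the het pathogenic site on this parent
        site = None
        for i in panel.pathogenic_indices:
            if dip.is_het(i):
                site = i
                break
        if site is None:
            out[parent] = "N"
            continue
        inherited = int(hap_vec[site])
        out[parent] = "P" if inherited == dip.pathogenic_hap else "N"
    return out


def _calls_concordant(calls: dict[str, FetalCall], truth: dict[str, str]) -> bool:
    for parent in ("mat", "pat"):
        if calls[parent].allele == "NO_CALL":
            return False
        if calls[parent].allele != truth[parent]:
            return False
    return True
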