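"""Genome QC filtering, HMO-utilization genotyping and AMR/virulence burden.

Genomes (isolates or MAGs) pass quality control when completeness >= 90%,
contamination <= 5%, N50 >= 10 kb, mean contig length >= 5 kb, at most 500
contigs and a passing chimerism (GUNC) flag; every boundary is inclusive.

Human-milk-oligosaccharide (HMO) substrate utilization is predicted by exact
gene-presence rules shipped as a versioned TSV: a substrate is positive when
any of its alternative enzyme sets is fully present and — in
``enzyme_and_transporter`` mode — any transporter alternative is present too.
2'-fucosyllactose (2'-FL) defaults to ``enzyme_only`` because the relevant
alpha-L-fucosidase (GH95/GH29) genotype occurs in strains with no known
2'-FL importer, yet such strains grow on 2'-FL in vitro; the strict joint
mode remains selectable. Gene identifiers match as exact strings after
case-folding.

AMR/virulence burden is the number of distinct resistance plus virulence
genes per genome; ESBL carriage flags the CTX-M/OXA/SHV/TEM families per
sample, requiring the curated ESBL class label on the hit.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeQC",
    "HMORule",
    "load_hmo_rules",
    "filter_genomes",
    "hmo_genotype",
    "genotype_prevalence",
    "amr_virulence_burden",
    "esbl_carriage",
    "ESBL_FAMILIES",
    "QC_THRESHOLDS",
]

QC_THRESHOLDS = {
    "completeness_min": 90.0,
    "contamination_max": 5.0,
    "n50_min": 10_000,
    "mean_contig_len_min": 5_000,
    "n_contigs_max": 500,
}

ESBL_FAMILIES = ("CTX-M", "OXA", "SHV", "TEM")


@dataclass
class GenomeQC:
    genome_id: str
    passed: bool
    failed_criteria: list

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_criteria)


@dataclass
class HMORule:
    substrate: str
    enzyme_sets: list  # alternatives; each a frozenset of required genes
    transporter_sets: list
    mode: str  # "enzyme_only" or "enzyme_and_transporter"

    def __post_init__(self) -> None:
        if not self.enzyme_sets:
            raise ValueError(f"{self.substrate}: at least one enzyme set required")
        if self.mode not in ("enzyme_only", "enzyme_and_transporter"):
            raise ValueError(f"unknown rule mode {self.mode!r}")


def _parse_alternatives(spec: str) -> list:
    alternatives = []
    for alt in str(spec).split("|"):
        genes = frozenset(g.strip().casefold() for g in alt.split("+") if g.strip())
        if genes:
            alternatives.append(genes)
    return alternatives


def load_hmo_rules(path=None) -> list[HMORule]:
    """Load HMO substrate rules from TSV (default: the shipped rule set).

    Columns: substrate, enzyme_alternatives, transporter_alternatives,
    default_mode. Alternatives are '|'-separated; genes within one
    alternative are '+'-joined (all required).
    """
    if path is None:
        text = resources.files("neostate").joinpath("data/hmo_rules.tsv").read_text()
        df = pd.read_csv(io.StringIO(text), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    rules = []
    for _, row in df.iterrows():
        rules.append(HMORule(
            substrate=str(row["substrate"]),
            enzyme_sets=_parse_alternatives(row["enzyme_alternatives"]),
            transporter_sets=_parse_alternatives(row.get("transporter_alternatives", "")),
            mode=str(row["default_mode"]),
        ))
    return rules


def filter_genomes(annotations: pd.DataFrame) -> list[GenomeQC]:
    """Apply the genome quality criteria; boundary equality passes.

    A genome with any missing QC field fails with reason ``missing_qc``. A
    ``gunc_pass`` boolean column is consumed if present (missing column means
    the test was not run and is not applied).
    """
    results = []
    has_gunc = "gunc_pass" in annotations.columns
    for _, row in annotations.iterrows():
        failed: list[str] = []
        qc_fields = ["completeness", "contamination", "n50", "mean_contig_len", "n_contigs"]
        if any(field not in row or pd.isna(row[field]) for field in qc_fields):
            failed.append("missing_qc")
        else:
            if row["completeness"] < QC_THRESHOLDS["completeness_min"]:
                failed.append("completeness")
            if row["contamination"] > QC_THRESHOLDS["contamination_max"]:
                failed.append("contamination")
            if row["n50"] < QC_THRESHOLDS["n50_min"]:
                failed.append("n50")
            if row["mean_contig_len"] < QC_THRESHOLDS["mean_contig_len_min"]:
                failed.append("mean_contig_len")
            if row["n_contigs"] > QC_THRESHOLDS["n_contigs_max"]:
                failed.append("n_contigs")
        if has_gunc and not pd.isna(row["gunc_pass"]) and not bool(row["gunc_pass"]):
            failed.append("gunc")
        results.append(GenomeQC(genome_id=str(row["genome_id"]), passed=not failed,
                                failed_criteria=failed))
    return results


def hmo_genotype(gene_families, rules: list[HMORule] | None = None,
                 mode_overrides: dict | None = None) -> dict:
    """Per-substrate utilization calls for one genome's gene-family set.

    A substrate is positive iff any enzyme alternative is fully present and,
    under ``enzyme_and_transporter`` mode, any transporter alternative is
    fully present as well. ``mode_overrides`` maps substrate to a mode,
    overriding each rule's default.
    """
    rules = rules if rules is not None else load_hmo_rules()
    mode_overrides = mode_overrides or {}
    present = {str(g).casefold() for g in gene_families}
    calls = {}
    for rule in rules:
        mode = mode_overrides.get(rule.substrate, rule.mode)
        if mode not in ("enzyme_only", "enzyme_and_transporter"):
            raise ValueError(f"unknown rule mode {mode!r}")
        enzyme_ok = any(s <= present for s in rule.enzyme_sets)
        if mode == "enzyme_only":
            calls[rule.substrate] = enzyme_ok
        else:
            transporter_ok = any(s <= present for s in rule.transporter_sets)
            calls[rule.substrate] = enzyme_ok and transporter_ok
    return calls


def genotype_prevalence(annotations: pd.DataFrame, rules: list[HMORule] | None = None,
                        mode_overrides: dict | None = None) -> pd.DataFrame:
    """Per-species HMO genotype prevalence (percentages to one decimal).

    Returns a tidy frame: species, substrate, positive, total, percentage.
    """
    rules = rules if rules is not None else load_hmo_rules()
    rows = []
    for species, grp in annotations.groupby("species"):
        if len(grp) == 0:
            raise ValueError(f"empty species group {species!r}")
        calls = pd.DataFrame(
            [hmo_genotype(g, rules, mode_overrides) for g in grp["gene_families"]]
        )
        for substrate in calls.columns:
            positive = int(calls[substrate].sum())
            total = len(calls)
            rows.append({
                "species": species, "substrate": substrate,
                "positive": positive, "total": total,
                "percentage": round(100.0 * positive / total, 1),
            })
    return pd.DataFrame(rows)


def _strip_class(token: str) -> str:
    return token.split("|", 1)[0]


def amr_virulence_burden(annotations: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Distinct AMR + virulence gene counts per genome, with per-species medians."""
    counts = []
    for _, row in annotations.iterrows():
        amr = {_strip_class(t).casefold() for t in row["amr_genes"]}
        vir = {str(t).casefold() for t in row["virulence_genes"]}
        counts.append({
            "genome_id": row["genome_id"], "species": row["species"],
            "n_amr": len(amr), "n_virulence": len(vir),
            "burden": len(amr) + len(vir),
        })
    per_genome = pd.DataFrame(counts).set_index("genome_id")
    medians = per_genome.groupby("species")["burden"].median()
    return per_genome, medians


def esbl_carriage(sample_hits: dict, states: pd.Series | None = None):
    """Per-sample ESBL family flags and, optionally, per-state carriage rates.

    ``sample_hits`` maps sample id to an iterable of gene tokens of the form
    ``symbol|class`` (the curated resistance class). A family flag is set iff
    a hit's symbol starts with that family prefix *and* its class label marks
    it as ESBL. Hits with unrecognized family prefixes are tallied and
    ignored.
    """
    rows = {}
    n_unknown = 0
    for sample, hits in sample_hits.items():
        flags = {fam: False for fam in ESBL_FAMILIES}
        for token in hits:
            symbol, _, klass = str(token).partition("|")
            if "ESBL" not in klass.upper():
                continue
            fam = next((f for f in ESBL_FAMILIES
                        if symbol.upper().startswith(f.replace("-", "")) or
                        symbol.upper().startswith(f)), None)
            if fam is None:
                n_unknown += 1
                continue
            flags[fam] = True
        rows[sample] = flags
    if n_unknown:
        logger.info("esbl_carriage: ignored %d hit(s) with unknown family prefix",
                    n_unknown)
    flags_df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")
    if states is None:
        return flags_df
    aligned = states.reindex(flags_df.index)
    per_state = flags_df.groupby(aligned).mean()
    return flags_df, per_state
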