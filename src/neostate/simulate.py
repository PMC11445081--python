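"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate the statistical structure of a neonatal gut
metagenome cohort:

* **Communities** — a three-component Dirichlet-multinomial mixture, one
  component per community state (BB, EF, BL), each dominated by a single
  driver species. Default state mix (17.6 / 43.4 / 38.9 %) and mean driver
  dominance (56.5 / 21.7 / 27.2 %) mirror the cohort-scale figures the
  pipeline is designed to reproduce.
* **Longitudinal trajectories** — per-participant Markov transitions of the
  week-1 state to day 21, stratified by birth mode (vaginal delivery VD vs
  caesarean CS), with default VD retention (0.92, 0.29, 0.89) for
  (BB, EF, BL), plus state-dependent driver-species carriage in infancy.
* **Covariates and outcomes** — clinical/sociodemographic covariates with a
  logistic link to state acquisition, including a confounded scenario
  (a distal confounder inflates the crude odds ratio of a proximal exposure).
* **Genome annotations** — per-species gene-family presence frequencies
  driving the HMO genotype rules, AMR/virulence hit lists and assembly QC
  statistics.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import AbundanceTable, CountTable

__all__ = [
    "CommunityConfig",
    "LongitudinalConfig",
    "CovariateConfig",
    "GenomeConfig",
    "simulate_states_counts",
    "simulate_longitudinal",
    "simulate_covariates_outcomes",
    "simulate_genomes",
    "simulate_sample_esbl_hits",
]

STATES = ("BB", "EF", "BL")
DRIVERS = {"BB": "B_breve", "EF": "E_faecalis", "BL": "B_longum"}


# ---------------------------------------------------------------- communities

@dataclass
class CommunityConfig:
    """Mixture of Dirichlet-multinomial communities with planted dominance."""

    n_samples: int = 1904
    n_species: int = 30
    states: tuple = STATES
    # BB, EF, BL state mix (exact cohort fractions; 17.6/43.4/38.9%)
    pi: tuple = (336 / 1904, 827 / 1904, 741 / 1904)
    dominance: tuple = (0.565, 0.217, 0.272)  # mean driver abundance per state
    concentration: float = 50.0
    depth: int = 10_000

    def species_ids(self) -> list[str]:
        ids = [DRIVERS[s] for s in self.states]
        ids += [f"sp_{i:02d}" for i in range(len(ids) + 1, self.n_species + 1)]
        return ids

    def alpha(self) -> np.ndarray:
        """Planted Dirichlet parameters: driver alpha = c*m, rest uniform."""
        K, S, c = len(self.states), self.n_species, self.concentration
        if any(not 0 < m < 1 for m in self.dominance):
            raise ValueError("dominance targets must lie in (0, 1)")
        alpha = np.empty((K, S))
        for k, m in enumerate(self.dominance):
            alpha[k] = c * (1 - m) / (S - 1)
            alpha[k, k] = c * m
        return alpha


def _draw_state_counts(rng, alpha_row, depth, size):
    p = rng.dirichlet(alpha_row, size=size)
    return np.array([rng.multinomial(depth, pi) for pi in p])


def simulate_states_counts(config: CommunityConfig | None = None, seed: int = 0):
    """Draw a cohort of communities from the planted mixture.

    Returns ``(counts, abundances, truth)``; ``truth`` holds each sample's
    true state, the planted mixture weights and the planted alpha matrix.
    """
    config = config if config is not None else CommunityConfig()
    rng = np.random.default_rng(seed)
    pi = np.asarray(config.pi, dtype=float)
    if abs(pi.sum() - 1) > 1e-9 or np.any(pi <= 0):
        raise ValueError("pi must be a positive simplex vector")
    alpha = config.alpha()
    components = rng.choice(len(config.states), size=config.n_samples, p=pi)
    counts = np.empty((config.n_samples, config.n_species), dtype=np.int64)
    for k in range(len(config.states)):
        idx = np.where(components == k)[0]
        if idx.size:
            counts[idx] = _draw_state_counts(rng, alpha[k], config.depth, idx.size)
    sample_ids = [f"S{i:05d}" for i in range(1, config.n_samples + 1)]
    cdf = pd.DataFrame(counts, index=sample_ids, columns=config.species_ids())
    count_table = CountTable(cdf, depth=config.depth)
    truth = {
        "state": pd.Series([config.states[k] for k in components], index=sample_ids),
        "pi": pi,
        "alpha": alpha,
        "driver_of_state": dict(DRIVERS),
    }
    return count_table, count_table.to_fractions(), truth


# -------------------------------------------------------------- longitudinal

def _transition_matrix(retention, initial_probs) -> np.ndarray:
    """Diagonal = retention; off-diagonal mass split by the other states' mix."""
    K = len(retention)
    T = np.zeros((K, K))
    p = np.asarray(initial_probs, dtype=float)
    for i in range(K):
        T[i, i] = retention[i]
        others = np.delete(np.arange(K), i)
        w = p[others]
        w = w / w.sum() if w.sum() > 0 else np.full(K - 1, 1.0 / (K - 1))
        T[i, others] = (1 - retention[i]) * w
    return T


@dataclass
class LongitudinalConfig:
    """Markov state dynamics across day 4/7/21 and infancy, by birth mode."""

    n_participants: int = 306
    vd_fraction: float = 140 / 306
    # week-1 state mix per birth mode (BB, EF, BL)
    initial_probs: dict = field(default_factory=lambda: {
        "VD": (26 / 140, 39 / 140, 75 / 140),
        "CS": (26 / 166, 114 / 166, 26 / 166),
    })
    # week-1 -> week-3 per-state retention per birth mode
    retention: dict = field(default_factory=lambda: {
        "VD": (0.92, 0.29, 0.89),
        "CS": (0.80, 0.39, 0.65),
    })
    day4_fraction: float = 0.06  # share of participants whose week-1 sample is day 4
    infancy_fraction: float = 0.9  # share resampled in infancy
    # P(driver species carried in infancy | week-1 state); rows = week-1 state
    infancy_carriage: dict = field(default_factory=lambda: {
        "BB": {"B_breve": 0.93, "E_faecalis": 0.44, "B_longum": 0.70},
        "EF": {"B_breve": 0.58, "E_faecalis": 0.44, "B_longum": 0.60},
        "BL": {"B_breve": 0.66, "E_faecalis": 0.36, "B_longum": 0.90},
    })
    community: CommunityConfig = field(default_factory=CommunityConfig)

    def transition_matrices(self) -> dict:
        return {
            mode: _transition_matrix(self.retention[mode], self.initial_probs[mode])
            for mode in ("VD", "CS")
        }


def simulate_longitudinal(config: LongitudinalConfig | None = None, seed: int = 0):
    """Per-participant state trajectories with re-drawn per-sample abundances.

    Returns ``(metadata, abundances, truth)``: a sample metadata table
    (sample_id, participant_id, day_of_life, birth_mode), one combined
    abundance table over all sampled timepoints, and a truth bundle with the
    per-sample true state, per-participant trajectories and the planted
    transition matrices.
    """
    config = config if config is not None else LongitudinalConfig()
    rng = np.random.default_rng(seed)
    comm = config.community
    alpha = comm.alpha()
    states = list(comm.states)
    trans = config.transition_matrices()

    meta_rows, count_rows, sample_states, traj = [], [], [], []
    sid = 0
    for p in range(config.n_participants):
        pid = f"P{p + 1:04d}"
        mode = "VD" if rng.random() < config.vd_fraction else "CS"
        s1 = int(rng.choice(len(states), p=config.initial_probs[mode]))
        s3 = int(rng.choice(len(states), p=trans[mode][s1]))
        week1_day = 4 if rng.random() < config.day4_fraction else 7
        schedule = [(week1_day, s1), (21, s3)]
        has_infancy = rng.random() < config.infancy_fraction
        if has_infancy:
            schedule.append((int(rng.integers(240, 330)), s3))
        for day, state_idx in schedule:
            sid += 1
            sample_id = f"L{sid:05d}"
            counts = _draw_state_counts(rng, alpha[state_idx], comm.depth, 1)[0]
            if day >= 180:
                # infancy: enforce state-dependent driver carriage
                week1_state = states[s1]
                for j, sp in enumerate(states):
                    driver = DRIVERS[sp]
                    p_carry = config.infancy_carriage[week1_state][driver]
                    if rng.random() > p_carry:
                        counts[j] = 0
                if counts.sum() == 0:
                    counts[len(states)] = comm.depth
            meta_rows.append({"sample_id": sample_id, "participant_id": pid,
                              "day_of_life": day, "birth_mode": mode})
            count_rows.append(counts)
            sample_states.append(states[state_idx])
        traj.append({"participant_id": pid, "birth_mode": mode,
                     "week1_state": states[s1], "day21_state": states[s3],
                     "sampled_infancy": has_infancy})

    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    counts = pd.DataFrame(count_rows, index=metadata.index, columns=comm.species_ids())
    abundance = AbundanceTable.from_dataframe(
        counts.div(counts.sum(axis=1), axis=0))
    truth = {
        "state": pd.Series(sample_states, index=metadata.index),
        "trajectories": pd.DataFrame(traj).set_index("participant_id"),
        "transition_matrices": trans,
        "retention": config.retention,
    }
    return metadata, abundance, truth


# ------------------------------------------------------- covariates/outcomes

@dataclass
class CovariateConfig:
    """Covariate tables with a logistic link to initial-state acquisition.

    ``effects`` maps covariate names to conditional log-odds-ratios on the
    one-vs-rest outcome; anything absent has no effect. In the confounded
    scenario a distal (maternal-block) confounder both raises the exposure
    probability and carries its own outcome effect, so the exposure's crude
    odds ratio exceeds its planted conditional value.
    """

    n: int = 1108
    outcome_state: str = "EF"
    baseline_prevalence: float = 0.434
    effects: dict = field(default_factory=lambda: {"cs_birth": np.log(2.3)})
    confounded: bool = False
    confounder_effect: float = np.log(3.5)
    confounder_exposure_logit: tuple = (-1.2, 2.2)  # P(exposure | confounder)


def simulate_covariates_outcomes(config: CovariateConfig | None = None, seed: int = 0):
    """Covariate table plus one-vs-rest outcomes with planted odds ratios.

    Returns ``(data, truth)``; ``data`` holds the covariates and a binary
    ``<state>_outcome`` column, ``truth`` the planted conditional ORs.
    """
    config = config if config is not None else CovariateConfig()
    rng = np.random.default_rng(seed)
    n = config.n
    data = pd.DataFrame(index=pd.RangeIndex(n))
    data["maternal_age_band"] = rng.choice(["<30", "30-39", ">=40"], size=n,
                                           p=[0.35, 0.55, 0.10])
    data["ethnicity"] = rng.choice(["white", "asian", "black", "other"], size=n,
                                   p=[0.70, 0.15, 0.08, 0.07])
    data["parity_first"] = rng.binomial(1, 0.55, size=n)
    if config.confounded:
        z = (data["maternal_age_band"] == ">=40").to_numpy(dtype=float)
        b0, b1 = config.confounder_exposure_logit
        p_cs = 1 / (1 + np.exp(-(b0 + b1 * z)))
        data["cs_birth"] = rng.binomial(1, p_cs)
    else:
        data["cs_birth"] = rng.binomial(1, 0.40, size=n)
    p_abx = np.where(data["cs_birth"] == 1, 0.90, 0.25)
    data["labour_abx"] = rng.binomial(1, p_abx)
    data["postnatal_abx"] = rng.binomial(1, 0.11, size=n)
    data["breastfeeding"] = rng.binomial(1, 0.85, size=n)

    eta = np.full(n, np.log(config.baseline_prevalence / (1 - config.baseline_prevalence)))
    for var, beta in config.effects.items():
        eta = eta + beta * data[var].to_numpy(dtype=float)
    if config.confounded:
        eta = eta + config.confounder_effect * (data["maternal_age_band"] == ">=40"
                                                ).to_numpy(dtype=float)
    # recentre so the marginal prevalence matches the configured baseline
    eta = eta - (np.mean(eta) - np.log(config.baseline_prevalence
                                       / (1 - config.baseline_prevalence)))
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    data[f"{config.outcome_state}_outcome"] = y
    truth = {
        "conditional_or": {v: float(np.exp(b)) for v, b in config.effects.items()},
        "confounder": ("maternal_age_band[>=40]" if config.confounded else None),
        "confounder_or": float(np.exp(config.confounder_effect)) if config.confounded else None,
        "outcome_state": config.outcome_state,
    }
    return data, truth


# ------------------------------------------------------------------- genomes

_DEFAULT_GENE_FREQS = {
    # frequencies of gene-family presence per species; chosen so the
    # rule-derived genotype prevalences resemble the cohort-scale pattern
    # (near-universal HMO repertoire in B. breve, partial in B. longum,
    # absent in E. faecalis)
    "B_breve": {"GH95": 0.976, "GH29": 0.10, "GH2": 0.99, "LacS": 0.99,
                "FumC": 0.99, "FumD": 0.99, "FumE": 0.99, "FumF": 0.99,
                "FumG": 0.99, "FucP": 0.97, "GH42": 0.99, "GH136": 0.30,
                "GltABC": 0.98, "GH20": 0.98, "Bbr_1554": 0.95, "GH112": 0.98},
    "B_longum": {"GH95": 0.049, "GH29": 0.0, "GH2": 0.99, "LacS": 0.98,
                 "FumC": 0.30, "FumD": 0.30, "FumE": 0.30, "FumF": 0.30,
                 "FumG": 0.30, "FucP": 0.25, "GH42": 0.95, "GH136": 0.20,
                 "GltABC": 0.95, "GH20": 0.40, "Bbr_1554": 0.0, "GH112": 0.92},
    "E_faecalis": {g: 0.0 for g in
                   ("GH95", "GH29", "GH2", "LacS", "FumC", "FumD", "FumE",
                    "FumF", "FumG", "FucP", "GH42", "GH136", "GltABC", "GH20",
                    "Bbr_1554", "GH112")},
}

_AMR_POOL = [f"amr_{i:03d}" for i in range(60)]
_VIR_POOL = [f"vf_{i:03d}" for i in range(60)]


@dataclass
class GenomeConfig:
    """Per-species genome annotation tables with planted genotype frequencies."""

    n_genomes: dict = field(default_factory=lambda: {
        "B_breve": 297, "E_faecalis": 561, "B_longum": 391})
    gene_freqs: dict = field(default_factory=lambda: {
        sp: dict(fr) for sp, fr in _DEFAULT_GENE_FREQS.items()})
    # combined AMR+virulence burden: (mean_amr, mean_virulence) Poisson rates
    burden_rates: dict = field(default_factory=lambda: {
        "B_breve": (0.2, 0.2), "B_longum": (0.3, 0.2), "E_faecalis": (9.0, 8.5)})
    qc_fail_fraction: float = 0.05


def simulate_genomes(config: GenomeConfig | None = None, seed: int = 0):
    """Genome annotation table (QC stats, gene families, AMR/virulence hits).

    Gene families are sampled independently per genome at the configured
    per-species frequencies. A configurable fraction of genomes is planted
    with a QC defect (low completeness, high contamination or low N50).
    Returns ``(annotations, truth)``.
    """
    config = config if config is not None else GenomeConfig()
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    for species, n in config.n_genomes.items():
        freqs = config.gene_freqs[species]
        genes = list(freqs)
        probs = np.array([freqs[g] for g in genes])
        amr_rate, vir_rate = config.burden_rates[species]
        for _ in range(n):
            gid += 1
            present = np.array(genes)[rng.random(len(genes)) < probs]
            n_amr = int(rng.poisson(amr_rate))
            n_vir = int(rng.poisson(vir_rate))
            amr = rng.choice(_AMR_POOL, size=min(n_amr, len(_AMR_POOL)), replace=False)
            vir = rng.choice(_VIR_POOL, size=min(n_vir, len(_VIR_POOL)), replace=False)
            completeness = float(np.clip(rng.normal(97, 2.0), 50, 100))
            contamination = float(np.clip(abs(rng.normal(1.0, 1.0)), 0, 30))
            n50 = int(rng.lognormal(np.log(50_000), 0.5))
            mean_contig = int(rng.lognormal(np.log(9_000), 0.4))
            n_contigs = int(rng.integers(40, 400))
            gunc_pass = True
            if rng.random() < config.qc_fail_fraction:
                defect = rng.integers(0, 3)
                if defect == 0:
                    completeness = float(rng.uniform(60, 89.9))
                elif defect == 1:
                    contamination = float(rng.uniform(5.1, 15))
                else:
                    n50 = int(rng.integers(1_000, 9_999))
            rows.append({
                "genome_id": f"G{gid:05d}", "species": species,
                "source": "isolate" if rng.random() < 0.1 else "MAG",
                "completeness": round(completeness, 2),
                "contamination": round(contamination, 2),
                "n50": n50, "mean_contig_len": mean_contig,
                "n_contigs": n_contigs, "gunc_pass": gunc_pass,
                "gene_families": tuple(present),
                "amr_genes": tuple(f"{g}|aminoglycoside" for g in amr),
                "virulence_genes": tuple(vir),
            })
    annotations = pd.DataFrame(rows).set_index("genome_id", drop=False)
    truth = {"gene_freqs": config.gene_freqs, "burden_rates": config.burden_rates,
             "qc_fail_fraction": config.qc_fail_fraction}
    return annotations, truth


def simulate_sample_esbl_hits(states: pd.Series, seed: int = 0,
                              family_probs: dict | None = None) -> dict:
    """Per-sample ESBL gene hit lists with state-dependent carriage.

    ``family_probs`` maps community state to per-family carriage probability;
    the default plants higher ESBL carriage in the EF and BL states.
    """
    rng = np.random.default_rng(seed)
    family_probs = family_probs or {
        "BB": {"CTX-M": 0.02, "OXA": 0.02, "SHV": 0.01, "TEM": 0.05},
        "EF": {"CTX-M": 0.15, "OXA": 0.08, "SHV": 0.06, "TEM": 0.20},
        "BL": {"CTX-M": 0.12, "OXA": 0.06, "SHV": 0.05, "TEM": 0.15},
    }
    exemplar = {"CTX-M": "CTX-M-15", "OXA": "OXA-1", "SHV": "SHV-12", "TEM": "TEM-1"}
    hits = {}
    for sample, state in states.items():
        probs = family_probs.get(state, {})
        sample_hits = [f"{exemplar[fam]}|ESBL" for fam, p in probs.items()
                       if rng.random() < p]
        hits[sample] = sample_hits
    return hits
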