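"""Ordination of the divergence matrix and driver-species attribution.

Principal coordinates analysis (PCoA) embeds the Jensen-Shannon divergence
matrix; an envfit-style permutation procedure then ranks species by how much
of the ordination-space variation their abundances explain (squared multiple
correlation R^2 against the first two axes, permutation p, Benjamini-Hochberg
q). Cramér's V measures concordance between two categorical state
assignments, e.g. the PAM and DMM routes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .assignments import StateAssignment
from .tables import AbundanceTable

__all__ = ["Ordination", "pcoa", "envfit_species", "cramers_v", "name_states_by_drivers"]


@dataclass
class Ordination:
    """PCoA embedding: centred coordinates and the positive eigenvalue spectrum."""

    sample_ids: list
    coordinates: np.ndarray  # (n, A)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    variance_explained: np.ndarray  # fractions of the positive-eigenvalue total
    negative_eigenvalues: np.ndarray  # reported, never embedded


def pcoa(D, n_axes: int = 2) -> Ordination:
    """Classical metric multidimensional scaling (Gower double-centring).

    Axes with negative eigenvalues (possible because raw JSD is not a metric)
    are discarded, and the variance-explained denominator is the sum of the
    positive eigenvalues only. Requesting more axes than there are positive
    eigenvalues truncates with a warning.
    """
    if isinstance(D, DistanceMatrix):
        A, ids = D.data, list(D.ids)
    else:
        A = np.asarray(D, dtype=float)
        ids = [str(i) for i in range(A.shape[0])]
    n = A.shape[0]
    B = -0.5 * A ** 2
    B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(np.abs(eigval).max(), 1.0) * 1e-10
    pos = eigval > tol
    pos_vals = eigval[pos]
    if n_axes > pos_vals.size:
        warnings.warn(
            f"requested {n_axes} axes but only {pos_vals.size} positive "
            "eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = pos_vals.size
    coords = eigvec[:, pos][:, :n_axes] * np.sqrt(pos_vals[:n_axes])
    return Ordination(
        sample_ids=ids,
        coordinates=coords,
        eigenvalues=pos_vals[:n_axes],
        variance_explained=pos_vals[:n_axes] / pos_vals.sum(),
        negative_eigenvalues=eigval[eigval < -tol],
    )


def envfit_species(ordination: Ordination, table: AbundanceTable,
                   n_perm: int = 999, seed: int = 0, n_axes: int = 2) -> pd.DataFrame:
    """Permutation attribution of species driving the ordination.

    For each species, its abundance vector is regressed (with intercept) on
    the first ``n_axes`` ordination coordinates; R^2 is the squared multiple
    correlation, and significance comes from permuting the species vector
    across samples: p = (1 + #{R^2_perm >= R^2_obs}) / (1 + n_perm).
    Benjamini-Hochberg q-values are computed across species. The result is
    ranked by R^2 descending; constant species get R^2 = 0, p = 1.
    """
    if list(ordination.sample_ids) != table.sample_ids:
        raise ValueError("sample order of ordination and table must match")
    coords = ordination.coordinates[:, :n_axes]
    n = coords.shape[0]
    # orthonormal basis of the centred axis space: R^2 = |Q^T yc|^2 / |yc|^2
    Q, _ = np.linalg.qr(coords - coords.mean(axis=0))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    rows = []
    Y = table.values
    for j, species in enumerate(table.species_ids):
        y = Y[:, j]
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot <= 1e-30:
            rows.append({"species_id": species, "r2": 0.0, "p_perm": 1.0,
                         "direction_1": 0.0, "direction_2": 0.0})
            continue
        proj = Q.T @ yc
        r2 = float(proj @ proj / ss_tot)
        perm_proj = Q.T @ yc[perms].T  # (n_axes, n_perm)
        perm_r2 = (perm_proj ** 2).sum(axis=0) / ss_tot
        p = (1 + int(np.sum(perm_r2 >= r2 - 1e-12))) / (1 + n_perm)
        beta = np.linalg.lstsq(coords - coords.mean(axis=0), yc, rcond=None)[0]
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        row = {"species_id": species, "r2": r2, "p_perm": p}
        for a in range(n_axes):
            row[f"direction_{a + 1}"] = float(direction[a])
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q_fdr"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    out = out.sort_values("r2", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def cramers_v(labels_a, labels_b) -> float:
    """Cramér's V association between two equal-length categorical labelings.

    V = sqrt(chi^2 / (n (min(r, c) - 1))) from the contingency table with no
    continuity correction; V = 0 by definition when either labeling has a
    single category.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 observations")
    ct = pd.crosstab(a, b)
    if min(ct.shape) < 2:
        return 0.0
    chi2 = chi2_contingency(ct.to_numpy(), correction=False)[0]
    v = np.sqrt(chi2 / (len(a) * (min(ct.shape) - 1)))
    return float(min(v, 1.0))


def name_states_by_drivers(assignment: StateAssignment, table: AbundanceTable,
                           driver_table: pd.DataFrame | None = None,
                           ordination: Ordination | None = None,
                           n_perm: int = 999, seed: int = 0) -> StateAssignment:
    """Rename raw cluster labels after each cluster's top driver species.

    The driver ranking comes from :func:`envfit_species` (supplied or computed
    here); each cluster is named after the highest-ranked driver species whose
    mean abundance peaks in that cluster, falling back to the cluster's most
    abundant species when the ranking does not separate clusters.
    """
    if driver_table is None:
        if ordination is None:
            from .diversity import jsd_matrix

            ordination = pcoa(jsd_matrix(table))
        driver_table = envfit_species(ordination, table, n_perm=n_perm, seed=seed)
    states = assignment.series
    mean_by_state = table.data.groupby(states).mean()  # states x species
    mapping: dict[str, str] = {}
    taken: set[str] = set()
    for species in driver_table["species_id"]:
        best_state = mean_by_state[species].idxmax()
        if best_state not in mapping:
            mapping[best_state] = species
            taken.add(species)
        if len(mapping) == assignment.k:
            break
    for state in mean_by_state.index:
        if state not in mapping:
            ranked = mean_by_state.loc[state].sort_values(ascending=False)
            fallback = next((s for s in ranked.index if s not in taken), ranked.index[0])
            mapping[state] = fallback
            taken.add(fallback)
    return assignment.rename(mapping)
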