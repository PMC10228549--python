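"""Community composition analyses on relative-abundance tables.

Covers presence accounting and the >=1 %-in-any-sample high-abundance
filter, per-experiment summaries of represented abundance, Bray-Curtis
dissimilarity, non-metric multidimensional scaling (NMDS, Kruskal
stress-1 minimized by alternating isotonic regression and a Guttman
transform, metaMDS-style with a PCoA start plus random restarts), and
PerMANOVA with Benjamini-Hochberg adjustment for pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests


@dataclass
class AbundanceTable:
    """Genomes x samples relative abundances (%) plus per-sample residual.

    Column sums of ``abundance`` plus ``residual`` equal 100.
    """

    abundance: pd.DataFrame  # rows: genome_id, columns: sample_id
    residual: pd.Series  # per sample, percent unmapped
    metadata: pd.DataFrame  # columns: sample_id, experiment, timepoint

    def __post_init__(self) -> None:
        if (self.abundance.values < -1e-9).any():
            raise ValueError("abundances must be non-negative")
        totals = self.abundance.sum(axis=0) + self.residual
        if not np.allclose(totals, 100.0, atol=1e-6):
            raise ValueError("per-sample totals (incl. residual) must equal 100")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def experiment_of(self) -> pd.Series:
        return self.metadata.set_index("sample_id")["experiment"].loc[self.sample_ids]

    def write(self, abundance_path: str | Path, metadata_path: str | Path) -> None:
        table = self.abundance.copy()
        table.loc["unmapped"] = self.residual
        table.index.name = "genome_id"
        table.to_csv(abundance_path, sep="\t", lineterminator="\n")
        self.metadata.to_csv(metadata_path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read(cls, abundance_path: str | Path, metadata_path: str | Path) -> "AbundanceTable":
        table = pd.read_csv(abundance_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t")
        if "unmapped" not in table.index:
            raise ValueError(f"{abundance_path} lacks the 'unmapped' residual row")
        residual = table.loc["unmapped"]
        return cls(table.drop(index="unmapped"), residual, metadata)


def presence_and_filter(
    table: AbundanceTable, presence_floor: float = 0.0, high_floor: float = 1.0
):
    """Presence sets per experiment, the high-abundance genome set, and
    per-experiment summaries of total represented abundance.

    A genome is *present* in a sample when abundance > ``presence_floor``
    and *high-abundance* when abundance >= ``high_floor`` in at least one
    sample anywhere.
    """
    if table.abundance.empty:
        raise ValueError("empty abundance table")
    exp = table.experiment_of()
    present: dict[str, set[str]] = {}
    rows = []
    for e in exp.unique():
        cols = exp.index[exp == e]
        sub = table.abundance[cols]
        present[e] = set(sub.index[(sub > presence_floor).any(axis=1)])
        represented = sub.sum(axis=0)
        rows.append({
            "experiment": e,
            "n_present": len(present[e]),
            "min_represented": round(float(represented.min()), 2),
            "max_represented": round(float(represented.max()), 2),
            "median_represented": round(float(represented.median()), 2),
        })
    high = set(table.abundance.index[(table.abundance >= high_floor).any(axis=1)])
    summary = pd.DataFrame(rows, columns=[
        "experiment", "n_present", "min_represented", "max_represented",
        "median_represented",
    ])
    return present, high, summary


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x, y)) / sum(x + y)."""
    return float(_scipy_braycurtis(np.asarray(x, float), np.asarray(y, float)))


def bray_curtis_matrix(table: AbundanceTable) -> pd.DataFrame:
    d = squareform(pdist(table.abundance.values.T, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


# -- NMDS -------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    stress: float  # Kruskal stress-1
    n_restarts: int
    converged: bool
    stress_trace: list[float] = field(default_factory=list)


def _pcoa_init(d: np.ndarray, k: int) -> np.ndarray:
    """Classical metric scaling (principal coordinates) start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    return coords


def _stress1(dhat: np.ndarray, dconf: np.ndarray) -> float:
    denom = float(np.sum(dconf**2))
    if denom == 0:
        return 1.0
    return float(np.sqrt(np.sum((dhat - dconf) ** 2) / denom))


def _nmds_single(d: np.ndarray, init: np.ndarray, max_iter: int, tol: float):
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    target = d[iu]
    order = np.argsort(target, kind="stable")
    iso = IsotonicRegression()
    x = init.copy()
    last = np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        dconf = squareform(pdist(x))[iu]
        dhat = np.empty_like(dconf)
        dhat[order] = iso.fit_transform(np.arange(order.size), dconf[order])
        # scale disparities to the configuration's sum of squares
        ss = np.sum(dhat**2)
        if ss > 0:
            dhat *= np.sqrt(np.sum(dconf**2) / ss)
        stress = _stress1(dhat, dconf)
        trace.append(stress)
        # Guttman transform
        full_dhat = squareform(dhat)
        full_dconf = squareform(dconf)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(full_dconf > 0, full_dhat / full_dconf, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = (b @ x) / n
        if abs(last - stress) < tol:
            converged = True
            break
        last = stress
    dconf = squareform(pdist(x))[iu]
    dhat = np.empty_like(dconf)
    dhat[order] = iso.fit_transform(np.arange(order.size), dconf[order])
    ss = np.sum(dhat**2)
    if ss > 0:
        dhat *= np.sqrt(np.sum(dconf**2) / ss)
    return x, _stress1(dhat, dconf), trace, converged


def nmds(
    distance,
    k: int = 2,
    n_restarts: int = 8,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    The first start is classical metric scaling (PCoA); the remaining
    restarts are seeded random configurations.  The best (lowest-stress)
    solution is reported.
    """
    labels = None
    if isinstance(distance, pd.DataFrame):
        labels = list(distance.index)
        d = distance.values.astype(float)
    else:
        d = np.asarray(distance, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(d) > 1e-12) or np.any(d < 0):
        raise ValueError("distance matrix must be non-negative with zero diagonal")
    n = d.shape[0]
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        init = _pcoa_init(d, k) if r == 0 else rng.normal(size=(n, k))
        x, stress, trace, converged = _nmds_single(d, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, trace, converged)
    x, stress, trace, converged = best
    coords = pd.DataFrame(
        x, index=labels if labels is not None else range(n),
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return OrdinationResult(
        coordinates=coords, stress=stress, n_restarts=max(1, n_restarts),
        converged=converged, stress_trace=trace,
    )


# -- PerMANOVA --------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = d2.shape[0]
    groups = np.unique(labels)
    a = groups.size
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    distance, labels, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns (pseudo-F, p) with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    d = distance.values if isinstance(distance, pd.DataFrame) else np.asarray(distance, float)
    labels = np.asarray(labels)
    if d.shape[0] != labels.size:
        raise ValueError("labels length must match distance matrix size")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = d**2
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (step-up), capped at 1."""
    p = np.asarray(pvalues, float)
    return multipletests(p, method="fdr_bh")[1]


def pairwise_permanova_bh(
    distance, labels, n_perm: int = 999, seed: int = 0, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise group contrasts with BH adjustment."""
    d = distance.values if isinstance(distance, pd.DataFrame) else np.asarray(distance, float)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(list(combinations(groups, 2))))
    for i, (g1, g2) in enumerate(combinations(groups, 2)):
        idx = np.nonzero((labels == g1) | (labels == g2))[0]
        f, p = permanova(
            d[np.ix_(idx, idx)], labels[idx], n_perm=n_perm,
            seed=int(child_seeds[i] % 2**31),
        )
        rows.append({"group1": g1, "group2": g2, "pseudo_F": f, "p_value": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p_value"].values)
    out["significant"] = out["p_adjusted"] < alpha
    return out
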