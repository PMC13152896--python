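"""Two-step discriminability statistics between the two white classes.

Step 1 is perceptual: the chromatic JND between the class centroids, where a
centroid is the per-cone geometric mean of the normalised quantum catches
(equivalently the arithmetic mean of the log-catches), with a percentile
bootstrap 95% confidence interval obtained by resampling specimens with
replacement within each class.  The estimate is read against the JND bands:
above 3 JND easily discriminable, 1-3 JND discriminable only under good
illumination, below 1 JND indistinguishable.

Step 2 is statistical: a one-way distance-based PERMANOVA on the pairwise
JND matrix, implemented from first principles.  Squared interpoint distances
are partitioned as

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_between = SS_total - SS_within
    pseudo-F = (SS_between / (a-1)) / (SS_within / (N-a))

with significance from random label permutations using the add-one
estimator p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .visual import VisualSystem, chromatic_distance, receptor_noise

JND_EASY = 3.0
JND_GOOD_LIGHT = 1.0


@dataclass
class BootDistResult:
    point_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_a: int
    n_b: int

    def verdict(self) -> str:
        return jnd_verdict(self.point_estimate)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_perm: int
    df_between: int
    df_within: int
    seed: int
    ss_between: float
    ss_within: float
    degenerate: bool = False


def jnd_verdict(jnd: float) -> str:
    """Map a chromatic distance onto the standard discriminability bands."""
    if jnd > JND_EASY:
        return "easily discriminable"
    if jnd >= JND_GOOD_LIGHT:
        return "discriminable only under good illumination"
    return "indistinguishable"


def centroid_distance(fA: np.ndarray, fB: np.ndarray, noise: np.ndarray) -> float:
    """JND between per-cone geometric-mean catches of two groups.

    ``fA``/``fB`` are (n, n_cones) log-catch matrices; the geometric mean of
    catches is the exponential of the mean log-catch, so the centroid in
    log-catch space is the column mean.
    """
    return chromatic_distance(fA.mean(axis=0), fB.mean(axis=0), noise)


def boot_coldist(
    fA: np.ndarray,
    fB: np.ndarray,
    vs: VisualSystem,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> BootDistResult:
    """Bootstrapped geometric-mean chromatic distance between two groups.

    Specimens are resampled with replacement within each group; the centroid
    distance is recomputed per replicate and the CI is the percentile
    interval of the bootstrap distribution.
    """
    fA = np.atleast_2d(np.asarray(fA, dtype=float))
    fB = np.atleast_2d(np.asarray(fB, dtype=float))
    if fA.shape[0] == 0 or fB.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(fA)) and np.all(np.isfinite(fB))):
        raise ValueError("log-catches must be finite (exclude catch-invalid spectra)")
    noise = receptor_noise(vs)
    point = centroid_distance(fA, fB, noise)

    rng = np.random.default_rng(seed)
    nA, nB = fA.shape[0], fB.shape[0]
    idxA = rng.integers(0, nA, size=(n_boot, nA))
    idxB = rng.integers(0, nB, size=(n_boot, nB))
    # vectorise: bootstrap centroids are means over resampled rows
    centA = fA[idxA].mean(axis=1)  # (n_boot, n_cones)
    centB = fB[idxB].mean(axis=1)
    df = centA - centB
    inv = 1.0 / noise**2
    x = (df @ inv) / inv.sum()
    ds = np.sqrt(np.sum((df - x[:, None]) ** 2 * inv, axis=1))
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(ds, [alpha, 1.0 - alpha])
    return BootDistResult(point, float(lo), float(hi), n_boot, seed, nA, nB)


def _group_ss(d2: np.ndarray, indicators: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """SS_within for each column of a (N, k) 0/1 group-indicator stack."""
    ss = np.zeros(indicators.shape[1])
    for g in range(sizes.size):
        mask = indicators == g
        X = mask.astype(float)
        ss += np.einsum("ik,ik->k", X, d2 @ X) / (2.0 * sizes[g])
    return ss


def _distinct_assignments(codes: np.ndarray) -> np.ndarray:
    """All distinct group assignments of the label multiset, as columns."""
    from itertools import permutations

    seen = sorted({p for p in permutations(codes.tolist())})
    return np.array(seen, dtype=codes.dtype).T


def permanova(
    D: np.ndarray,
    labels: np.ndarray | list,
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way distance-based PERMANOVA with permutation p-value.

    ``D`` is a symmetric distance matrix (array or DataFrame), ``labels`` the
    group assignment per row.  Requires at least two groups with at least two
    members each.  An all-zero distance matrix yields a degenerate result
    (pseudo-F 0, p 1) rather than a division by zero.  With ``exhaustive``
    (feasible only for small samples) every distinct relabelling is
    enumerated and p is the exact proportion of relabellings with
    F >= F_observed (the observed labelling included).
    """
    D = np.asarray(getattr(D, "values", D), dtype=float)
    labels = np.asarray([str(l) for l in np.asarray(labels)])
    N = D.shape[0]
    if D.shape != (N, N):
        raise ValueError("distance matrix must be square")
    if labels.size != N:
        raise ValueError("one label per row required")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = uniq.size
    sizes = np.bincount(codes)
    if a < 2:
        raise ValueError("need at least two groups")
    if np.any(sizes < 2):
        small = uniq[sizes < 2]
        raise ValueError(f"singleton group(s): {list(small)}")

    d2 = D**2
    ss_total = d2.sum() / (2.0 * N)
    if ss_total <= 0:
        return PermanovaResult(0.0, 1.0, n_perm, a - 1, N - a, seed, 0.0, 0.0, True)

    def f_stat(code_cols: np.ndarray) -> np.ndarray:
        ss_within = _group_ss(d2, code_cols, sizes)
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (N - a))

    F_obs = float(f_stat(codes[:, None])[0])
    if exhaustive:
        perms = _distinct_assignments(codes)
        n_perm = perms.shape[1]
        F_perm = f_stat(perms)
        p = float(np.sum(F_perm >= F_obs - 1e-12)) / n_perm
    else:
        rng = np.random.default_rng(seed)
        perms = np.empty((N, n_perm), dtype=codes.dtype)
        for k in range(n_perm):
            perms[:, k] = rng.permutation(codes)
        F_perm = f_stat(perms)
        p = (1.0 + np.sum(F_perm >= F_obs - 1e-12)) / (1.0 + n_perm)
    ss_within = float(_group_ss(d2, codes[:, None], sizes)[0])
    return PermanovaResult(
        F_obs, float(p), n_perm, a - 1, N - a, seed, ss_total - ss_within, ss_within
    )


@dataclass
class TwoStepReport:
    boot: BootDistResult | None
    perm: PermanovaResult | None
    verdict: str
    note: str = ""


def two_step_report(
    f_by_label: dict[str, np.ndarray],
    D: np.ndarray,
    d_labels: np.ndarray | list,
    vs: VisualSystem,
    class_a: str = "UVplus_white",
    class_b: str = "UVminus_white",
    n_boot: int = 1000,
    n_perm: int = 9999,
    seed: int = 0,
) -> TwoStepReport:
    """Combined perceptual + statistical report for the two white classes.

    ``f_by_label`` maps class label to its (n, n_cones) log-catch matrix;
    ``D`` and ``d_labels`` are the pairwise JND matrix and its per-row labels
    restricted to the same two classes.  With fewer than two classes present
    the report declines the two-class statistics with an explanation instead
    of failing.
    """
    present = [c for c in (class_a, class_b) if c in f_by_label and len(f_by_label[c]) > 0]
    if len(present) < 2:
        return TwoStepReport(
            None,
            None,
            verdict="not assessed",
            note=(
                "two-class statistics require both white classes; "
                f"present: {present or 'none'}"
            ),
        )
    boot = boot_coldist(
        f_by_label[class_a], f_by_label[class_b], vs, n_boot=n_boot, seed=seed
    )
    d_labels = np.asarray([str(l) for l in np.asarray(d_labels)])
    keep = np.isin(d_labels, [class_a, class_b])
    D = np.asarray(getattr(D, "values", D), dtype=float)
    perm = permanova(D[np.ix_(keep, keep)], d_labels[keep], n_perm=n_perm, seed=seed)
    return TwoStepReport(boot, perm, verdict=boot.verdict())
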