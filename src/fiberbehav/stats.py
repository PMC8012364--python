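"""Bootstrap elevated-window detection and frame-wise permutation tests.

Subject-level mean traces (subjects x frames, z units) are the test input.
The bootstrap resamples subjects with replacement (5000 iterations,
two-sided alpha 0.001 by default) and flags frames whose lower percentile
bound excludes the z = 0 baseline; frame-wise permutation tests compare two
groups (or two outcomes within subjects, paired) at alpha 0.01. In both
cases singleton significant frames - frames with no significant neighbor -
are filtered out before contiguous windows are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from statsmodels.stats.multitest import multipletests


@dataclass
class BootstrapResult:
    """Per-frame percentile bounds of the bootstrap distribution of the mean."""

    lower: np.ndarray
    upper: np.ndarray
    n_iter: int
    alpha: float
    seed: int | None = None

    def __post_init__(self):
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower bound above upper bound")


@dataclass
class SignificanceMask:
    """Per-frame significance plus contiguous windows after filtering."""

    mask: np.ndarray
    frame_times_s: np.ndarray | None = None
    windows: list = field(default_factory=list)  # (start_s, end_s) half-open
    meta: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.mask))


def singleton_filter(mask: np.ndarray, min_run: int = 2) -> np.ndarray:
    """Remove runs of True shorter than ``min_run``; longer runs untouched."""
    mask = np.asarray(mask, dtype=bool).copy()
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i < min_run:
                mask[i:j] = False
            i = j
        else:
            i += 1
    return mask


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs, half-open."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def _windows_from_mask(mask, frame_times_s, fs_hint=None):
    if frame_times_s is None:
        return [(int(a), int(b)) for a, b in _runs(mask)]
    t = np.asarray(frame_times_s, dtype=float)
    dt = fs_hint or (t[1] - t[0] if t.size > 1 else 0.0)
    return [(float(t[a]), float(t[b - 1] + dt)) for a, b in _runs(mask)]


def bootstrap_mean_ci(
    traces: np.ndarray,
    n_iter: int = 5000,
    alpha: float = 0.001,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Percentile bootstrap interval for the group-mean trace.

    Each iteration draws ``n_subjects`` subject traces with replacement and
    averages them; per frame the bounds are the empirical alpha/2 and
    1 - alpha/2 quantiles of the ``n_iter`` resampled means.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_subj = traces.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    draws = rng.integers(0, n_subj, size=(n_iter, n_subj))
    boot_means = traces[draws].mean(axis=1)  # n_iter x frames
    lower = np.quantile(boot_means, alpha / 2.0, axis=0)
    upper = np.quantile(boot_means, 1.0 - alpha / 2.0, axis=0)
    return BootstrapResult(lower=lower, upper=upper, n_iter=n_iter,
                           alpha=alpha, seed=seed)


def bootstrap_mean_ci_trialwise(
    trial_matrices: list,
    n_iter: int = 5000,
    alpha: float = 0.001,
    seed: int | None = None,
) -> BootstrapResult:
    """Alternative construction: per-subject trial bootstrap, bounds averaged.

    For each subject its trials are resampled with replacement to form a
    per-subject percentile interval of the subject-mean trace; the group
    bounds are the averages of the per-subject bounds.
    """
    rng = np.random.default_rng(seed)
    lowers, uppers = [], []
    for mat in trial_matrices:
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        n_tr = mat.shape[0]
        draws = rng.integers(0, n_tr, size=(n_iter, n_tr))
        boot = mat[draws].mean(axis=1)
        lowers.append(np.quantile(boot, alpha / 2.0, axis=0))
        uppers.append(np.quantile(boot, 1.0 - alpha / 2.0, axis=0))
    return BootstrapResult(
        lower=np.mean(lowers, axis=0), upper=np.mean(uppers, axis=0),
        n_iter=n_iter, alpha=alpha, seed=seed,
    )


def elevated_windows(
    result: BootstrapResult,
    frame_times_s: np.ndarray | None = None,
    min_run: int = 2,
) -> SignificanceMask:
    """Frames whose lower bootstrap bound exceeds the z = 0 baseline.

    Runs shorter than ``min_run`` frames are removed (singleton filtering);
    the surviving runs are reported as half-open (start_s, end_s) windows.
    """
    raw = result.lower > 0
    mask = singleton_filter(raw, min_run=min_run)
    return SignificanceMask(
        mask=mask,
        frame_times_s=frame_times_s,
        windows=_windows_from_mask(mask, frame_times_s),
        meta={"alpha": result.alpha, "n_iter": result.n_iter,
              "comparison": "elevated_vs_baseline", "min_run": min_run},
    )


def permutation_difference_mask(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_iter: int = 5000,
    alpha: float = 0.01,
    paired: bool = False,
    min_run: int = 2,
    seed: int | None = None,
    return_pvalues: bool = False,
):
    """Frame-wise permutation test of the difference of group means.

    Unpaired: subject-to-group labels are reshuffled; paired: within-subject
    label swaps (random sign flips of the per-subject difference). Two-sided
    Monte-Carlo p per frame with the +1 correction,
    ``p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_iter)``; a frame is
    significant iff p < alpha, then singleton filtering is applied.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the frame grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired mode requires matched subjects")
        diff = a - b
        t_obs = diff.mean(axis=0)
        signs = rng.choice([-1.0, 1.0], size=(n_iter, diff.shape[0]))
        t_perm = (signs[:, :, None] * diff[None, :, :]).mean(axis=1)
    else:
        pooled = np.vstack([a, b])
        n_a, n_tot = a.shape[0], a.shape[0] + b.shape[0]
        t_obs = a.mean(axis=0) - b.mean(axis=0)
        order = np.argsort(rng.random((n_iter, n_tot)), axis=1)
        perm_a = pooled[order[:, :n_a]].mean(axis=1)
        perm_b = pooled[order[:, n_a:]].mean(axis=1)
        t_perm = perm_a - perm_b
    # tolerance so exact ties (e.g. the identity permutation) count as
    # exceedances regardless of floating-point summation order
    tol = 1e-9 * (np.abs(t_obs) + 1e-12)
    exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :] - tol).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_iter)
    raw = pvals < alpha
    mask = singleton_filter(raw, min_run=min_run)
    sig = SignificanceMask(
        mask=mask,
        windows=_windows_from_mask(mask, None),
        meta={"alpha": alpha, "n_iter": n_iter,
              "comparison": "paired" if paired else "unpaired",
              "min_run": min_run, "raw_mask": raw},
    )
    if return_pvalues:
        return sig, pvals
    return sig


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR: ``(adjusted_p, reject_flags)``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
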