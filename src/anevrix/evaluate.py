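"""Patient-wise detection scoring and the supporting statistics.

A candidate hits a lesion when the candidate's centre of mass lies within
the lesion's maximum diameter of the lesion centroid. FROC curves sweep the
detection threshold; per-subject areas are normalized trapezoids capped at
a fixed false-positive budget. Wilson intervals, the exact/approximate
Wilcoxon signed-rank test and Pearson chi-squared complete the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .annotate import MaskStats
from .infer import Candidate

__all__ = ["DetectionResult", "FrocCurve", "match_detections", "froc",
           "wilson_ci", "wilcoxon_signed_rank", "chi_squared"]


@dataclass
class DetectionResult:
    matched: list[tuple[Candidate, int]]   # (candidate, lesion index)
    false_positives: list[Candidate]
    missed_lesions: list[int]
    threshold: float | None = None

    @property
    def n_hits(self) -> int:
        return len(self.matched)

    @property
    def n_fp(self) -> int:
        return len(self.false_positives)

    def sensitivity(self, n_lesions: int) -> float:
        if n_lesions == 0:
            raise ValueError("sensitivity undefined without lesions")
        return self.n_hits / n_lesions


def match_detections(
    cands: list[Candidate],
    lesions: list[MaskStats],
    floor_mm: float = 0.0,
    threshold: float | None = None,
) -> DetectionResult:
    """Greedy candidate-to-lesion assignment in descending score order.

    Candidate c hits lesion g iff ||c.center - g.centroid|| <=
    max(g.max_diameter, floor_mm). Each lesion is consumed once; extra hits
    on an already-matched lesion are discarded (neither TP nor FP).
    """
    order = sorted(range(len(cands)),
                   key=lambda i: (-cands[i].score, -cands[i].voxel_count,
                                  cands[i].center))
    taken = [False] * len(lesions)
    matched: list[tuple[Candidate, int]] = []
    fps: list[Candidate] = []
    for i in order:
        c = cands[i]
        center = np.asarray(c.center)
        hit_idx = None
        hit_taken = False
        for j, g in enumerate(lesions):
            d = float(np.linalg.norm(center - np.asarray(g.centroid)))
            if d <= max(g.max_diameter, floor_mm):
                if taken[j]:
                    hit_taken = True
                else:
                    hit_idx = j
                    break
        if hit_idx is not None:
            taken[hit_idx] = True
            matched.append((c, hit_idx))
        elif not hit_taken:
            fps.append(c)
    missed = [j for j, t in enumerate(taken) if not t]
    return DetectionResult(matched, fps, missed, threshold)


@dataclass
class FrocCurve:
    thresholds: list[float]            # descending
    fp_per_subject: list[float]
    sensitivity: list[float]
    per_subject_auc: dict[str, float]
    fp_cap: float


def _subject_auc(fp_counts, sens, fp_cap: float) -> float:
    """Trapezoid of sensitivity over FP count, extended to fp_cap, /fp_cap."""
    pts = sorted(zip(fp_counts, sens))
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    xs.append(max(fp_cap, xs[-1]))
    ys.append(ys[-1])
    area = 0.0
    for (x0, y0), (x1, y1) in zip(zip(xs[:-1], ys[:-1]), zip(xs[1:], ys[1:])):
        lo, hi = min(x0, fp_cap), min(x1, fp_cap)
        if hi > lo:
            # linear interp of y at clipped ends
            if x1 == x0:
                ya, yb = y0, y1
            else:
                ya = y0 + (y1 - y0) * (lo - x0) / (x1 - x0)
                yb = y0 + (y1 - y0) * (hi - x0) / (x1 - x0)
            area += 0.5 * (ya + yb) * (hi - lo)
    return area / fp_cap


def froc(
    per_subject_candidates: dict[str, list[Candidate]],
    per_subject_lesions: dict[str, list[MaskStats]],
    thresholds=None,
    fp_cap: float = 5.0,
    floor_mm: float = 0.0,
) -> FrocCurve:
    """Threshold sweep over candidate scores.

    Subjects without lesions contribute to the FP mean only. Per-subject
    AUC is the capped, normalized trapezoid of sensitivity vs FP count.
    """
    if thresholds is None:
        thresholds = [round(0.95 - 0.05 * i, 2) for i in range(19)]
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be sorted descending")
    subjects = sorted(per_subject_candidates)
    fp_means: list[float] = []
    sens_means: list[float] = []
    per_subj_fp = {s: [] for s in subjects}
    per_subj_sens = {s: [] for s in subjects}
    for thr in thresholds:
        fps, senss = [], []
        for s in subjects:
            cands = [c for c in per_subject_candidates[s] if c.score >= thr]
            lesions = per_subject_lesions.get(s, [])
            res = match_detections(cands, lesions, floor_mm=floor_mm, threshold=thr)
            fps.append(res.n_fp)
            per_subj_fp[s].append(res.n_fp)
            if lesions:
                sv = res.sensitivity(len(lesions))
                senss.append(sv)
                per_subj_sens[s].append(sv)
        fp_means.append(float(np.mean(fps)) if fps else 0.0)
        sens_means.append(float(np.mean(senss)) if senss else 0.0)
    auc = {}
    for s in subjects:
        if per_subject_lesions.get(s):
            auc[s] = _subject_auc(per_subj_fp[s], per_subj_sens[s], fp_cap)
    return FrocCurve(thresholds, fp_means, sens_means, auc, fp_cap)


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    z = float(stats.norm.ppf(0.5 + conf / 2.0))
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def _signed_rank_exact_p(ranks: np.ndarray, w_min: float) -> float:
    """P(min(W+,W-) <= w_min) * appropriate two-sidedness via the null DP.

    Uses the exact distribution of W+ over all 2^n sign patterns, computed
    by dynamic programming; the two-sided p is 2 * P(W+ <= w_min), capped
    at 1 (W+ is symmetric under the null).
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    cdf = counts.cumsum() / counts.sum()
    p = 2.0 * cdf[int(round(w_min))]
    return min(1.0, p)


def wilcoxon_signed_rank(x, y) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test; returns (W, p, n_effective).

    Zero differences are dropped; |d| are ranked with midranks. The exact
    null distribution (full sign enumeration) is used when n <= 20 and
    there are no ties; otherwise a normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be nonempty and equal-length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 20 and not has_ties:
        p = _signed_rank_exact_p(ranks, w)
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts ** 3 - tie_counts).sum()) / 48.0
        z = (w - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.cdf(z)))
    return w, p, n


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared on an r x c count table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2D array of nonnegative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row <= 0) or np.any(col <= 0):
        raise ValueError("all row and column sums must be positive")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    return chi2, dof, p
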