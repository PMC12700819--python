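"""Contact-map construction and statistics.

Covers the full quantification stack used on region-capture Micro-C style
maps and on simulated conformations: map binning from 3D trajectories, ICE
balancing, contact-probability scaling P(s) and its log-log derivative,
local-background (21x21 window) and observed/expected loop strengths,
simulation 6-kb window strengths, aggregate peak analysis (APA) pileups,
anchor classification (promoter / enhancer / CTCF-cohesin / other, inclusive
or exclusive), compartment eigendecomposition and loop-compartment
categorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "ContactMap",
    "LoopTable",
    "AnchorAnnotation",
    "contact_map_from_trajectory",
    "ice_balance",
    "contact_scaling",
    "local_background_matrix",
    "loop_strength",
    "sim_window_strength",
    "apa_pileup",
    "classify_anchors",
    "classify_loops",
    "compartment_call",
    "classify_loop_compartments",
]

LOOP_CLASSES = ("P-P", "E-P", "E-E", "E/P-CTCF", "CTCF-CTCF", "other")
ANCHOR_CLASSES = ("promoter", "enhancer", "ctcf", "other")


@dataclass
class ContactMap:
    """Symmetric binned contact matrix with bin table and balancing weights."""

    matrix: np.ndarray
    resolution: int  # bp per bin
    chrom: str = "chrS"
    start: int = 0
    weights: np.ndarray | None = None
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_table(self) -> pd.DataFrame:
        starts = self.start + self.resolution * np.arange(self.n_bins)
        return pd.DataFrame({"chrom": self.chrom, "start": starts, "end": starts + self.resolution})

    def balanced(self) -> np.ndarray:
        """diag(w) @ M @ diag(w); NaN on masked bins."""
        if self.weights is None:
            raise ValueError("map has no balancing weights; run ice_balance first")
        return self.matrix * np.outer(self.weights, self.weights)

    def bin_of(self, pos_bp: int) -> int:
        return int((pos_bp - self.start) // self.resolution)


@njit(cache=True)
def _count_contacts(frames, radius2, counts):
    n_frames, n, _ = frames.shape
    for f in range(n_frames):
        for i in range(n):
            counts[i, i] += 1.0
            for j in range(i + 1, n):
                dx = frames[f, i, 0] - frames[f, j, 0]
                dy = frames[f, i, 1] - frames[f, j, 1]
                dz = frames[f, i, 2] - frames[f, j, 2]
                if dx * dx + dy * dy + dz * dz <= radius2:
                    counts[i, j] += 1.0
                    counts[j, i] += 1.0


def contact_map_from_trajectory(
    trajectory,
    contact_radius: float = 4.0,
    bin_monomers: int = 4,
    sigma_kb: float = 0.5,
    a: float = 1.0,
) -> ContactMap:
    """Bin monomer-pair contacts (spatial distance <= ``contact_radius * a``)
    aggregated over all frames; default 4-monomer radius and 4-monomer (2 kb)
    bins."""
    frames = np.ascontiguousarray(trajectory.frames, dtype=np.float64)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("trajectory must contain at least one frame")
    n = frames.shape[1]
    n_bins = n // bin_monomers
    if n_bins < 2:
        raise ValueError(f"bin of {bin_monomers} monomers does not divide {n} into >= 2 bins")
    counts = np.zeros((n, n))
    _count_contacts(frames, (contact_radius * a) ** 2, counts)
    m = n_bins * bin_monomers
    binned = counts[:m, :m].reshape(n_bins, bin_monomers, n_bins, bin_monomers).sum(axis=(1, 3))
    binned = (binned + binned.T) / 2.0
    return ContactMap(binned, resolution=int(bin_monomers * sigma_kb * 1000), provenance="simulated")


def ice_balance(cmap: ContactMap, max_iter: int = 500, tol: float = 1e-8) -> ContactMap:
    """Iterative correction: find weights w so that diag(w) M diag(w) has
    equal row sums on unmasked bins.  All-zero rows are masked (weight NaN)."""
    m = cmap.matrix
    if np.any(m < 0):
        raise ValueError("contact matrix must be non-negative")
    n = m.shape[0]
    mask = m.sum(axis=1) > 0
    w = np.ones(n)
    w[~mask] = np.nan
    sub = m[np.ix_(mask, mask)].copy()
    ws = np.ones(sub.shape[0])
    converged = False
    for _ in range(max_iter):
        s = (sub * np.outer(ws, ws)).sum(axis=1)
        s /= s.mean()
        if np.max(np.abs(s - 1.0)) < tol:
            converged = True
            break
        ws /= np.sqrt(s)
    if not converged:
        warnings.warn("ICE did not converge within max_iter; returning best iterate")
    # normalize so the balanced matrix mean matches the raw mean scale
    w[mask] = ws
    out = ContactMap(m.copy(), cmap.resolution, cmap.chrom, cmap.start, weights=w, provenance=cmap.provenance)
    out.ice_converged = converged  # type: ignore[attr-defined]
    return out


def expected_by_distance(matrix: np.ndarray) -> np.ndarray:
    """Mean value per diagonal (genomic separation in bins), NaN-aware."""
    n = matrix.shape[0]
    out = np.empty(n)
    for s in range(n):
        d = np.diagonal(matrix, offset=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[s] = np.nanmean(d) if len(d) else np.nan
    return out


def contact_scaling(
    cmap: ContactMap,
    bin_ratio: float = 1.12,
    max_separation_bins: int | None = None,
    smooth_window: int = 5,
    use_balanced: bool = False,
) -> pd.DataFrame:
    """P(s) on log-spaced separation bins plus the log-log first derivative.

    Returns a DataFrame with columns ``s_bp`` (geometric bin center),
    ``p`` (mean contact probability, normalized to the first bin) and
    ``dlogp_dlogs`` (centered differences on the log-smoothed curve; NaN where
    undefined).
    """
    mat = cmap.balanced() if use_balanced else cmap.matrix
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 bins")
    smax = n - 1 if max_separation_bins is None else min(max_separation_bins, n - 1)
    per_diag = expected_by_distance(mat)[1 : smax + 1]
    seps = np.arange(1, smax + 1, dtype=float)
    # log-spaced bins with the given ratio
    edges = [1.0]
    while edges[-1] < smax + 1:
        edges.append(edges[-1] * bin_ratio)
    edges = np.array(edges)
    idx = np.digitize(seps, edges) - 1
    centers, means = [], []
    for b in range(idx.max() + 1):
        sel = idx == b
        if not sel.any() or np.all(np.isnan(per_diag[sel])):
            continue
        centers.append(np.exp(np.nanmean(np.log(seps[sel]))))
        means.append(np.nanmean(per_diag[sel]))
    centers = np.array(centers)
    means = np.array(means)
    if len(centers) < 2:
        return pd.DataFrame({"s_bp": centers * cmap.resolution, "p": means, "dlogp_dlogs": np.full(len(centers), np.nan)})
    with np.errstate(divide="ignore"):
        logp = np.log(means)
    logs = np.log(centers)
    # moving-average smoothing in log space before differencing
    if smooth_window > 1 and len(logp) > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(logp, pad, mode="edge")
        logp_s = np.convolve(padded, kernel, mode="valid")[: len(logp)]
    else:
        logp_s = logp
    deriv = np.full(len(logp), np.nan)
    deriv[1:-1] = (logp_s[2:] - logp_s[:-2]) / (logs[2:] - logs[:-2])
    p0 = means[0] if means[0] > 0 else 1.0
    return pd.DataFrame({"s_bp": centers * cmap.resolution, "p": means / p0, "dlogp_dlogs": deriv})


def _window_bounds(center: int, halfwidth: int, n: int) -> tuple[int, int]:
    return center - halfwidth, center + halfwidth + 1


def local_background_matrix(
    cmap: ContactMap,
    loop_bins: tuple[int, int],
    halfwidth: int = 10,
    flank_bins: int | None = None,
    use_balanced: bool = True,
) -> np.ndarray:
    """Local distance-decay background for a loop: entry (di, dj) is the mean
    of all map elements at the same genomic separation whose two anchors lie
    within ``flank_bins`` (default 100 kb worth of bins) of the corresponding
    window cell.  Loops closer to the diagonal than the window half-width are
    rejected (strength quantification excludes loops shorter than 10 kb).
    """
    i0, j0 = int(loop_bins[0]), int(loop_bins[1])
    if j0 < i0:
        i0, j0 = j0, i0
    mat = cmap.balanced() if use_balanced else cmap.matrix
    n = mat.shape[0]
    if flank_bins is None:
        flank_bins = max(int(round(100_000 / cmap.resolution)), halfwidth)
    if j0 - i0 <= 2 * halfwidth:
        raise ValueError(
            f"loop separation {j0 - i0} bins is within the {2 * halfwidth + 1}-bin window of the diagonal"
        )
    if not (0 <= i0 - halfwidth and j0 + halfwidth < n):
        raise ValueError("loop window extends beyond map bounds")
    size = 2 * halfwidth + 1
    bg = np.empty((size, size))
    for a_off in range(-halfwidth, halfwidth + 1):
        for b_off in range(-halfwidth, halfwidth + 1):
            u0, v0 = i0 + a_off, j0 + b_off
            s = v0 - u0
            lo = max(u0 - flank_bins, 0)
            hi = min(u0 + flank_bins, n - 1 - s)
            us = np.arange(lo, hi + 1)
            vals = mat[us, us + s]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                bg[a_off + halfwidth, b_off + halfwidth] = np.nanmean(vals)
    return bg


def loop_strength(
    cmap: ContactMap,
    loop_bins: tuple[int, int],
    mode: str = "obs_over_exp",
    halfwidth: int = 10,
    flank_bins: int | None = None,
) -> float:
    """Scalar loop strength within the (2*halfwidth+1)^2 window.

    ``bg_subtracted``: sum(observed) - sum(local background).
    ``obs_over_exp``: sum(observed) / sum(local background).
    ``total``: sum(observed) alone.
    Balanced values are used when weights are present.
    """
    if mode not in ("bg_subtracted", "obs_over_exp", "total"):
        raise ValueError(f"unknown mode {mode!r}")
    i0, j0 = sorted(int(b) for b in loop_bins)
    use_balanced = cmap.weights is not None
    mat = cmap.balanced() if use_balanced else cmap.matrix
    lo_i, hi_i = _window_bounds(i0, halfwidth, mat.shape[0])
    lo_j, hi_j = _window_bounds(j0, halfwidth, mat.shape[0])
    if lo_i < 0 or hi_j > mat.shape[0]:
        raise ValueError("loop window extends beyond map bounds")
    obs = np.nansum(mat[lo_i:hi_i, lo_j:hi_j])
    if mode == "total":
        return float(obs)
    bg = local_background_matrix(cmap, (i0, j0), halfwidth, flank_bins, use_balanced=use_balanced)
    exp_sum = np.nansum(bg)
    if mode == "bg_subtracted":
        return float(obs - exp_sum)
    if exp_sum == 0 or not np.isfinite(exp_sum):
        return float("nan")
    return float(obs / exp_sum)


def sim_window_strength(
    cmap: ContactMap,
    pair_bins: tuple[int, int],
    window_kb: float = 6.0,
    relative: bool = False,
) -> float:
    """Mean contacts in a ``window_kb`` x ``window_kb`` square centered on a
    site pair (3x3 bins at 2-kb resolution); ``relative`` divides by the
    map-wide mean number of contacts at the corresponding separations."""
    hw = int(round(window_kb * 1000 / cmap.resolution)) // 2
    i0, j0 = sorted(int(b) for b in pair_bins)
    n = cmap.n_bins
    if i0 - hw < 0 or j0 + hw >= n:
        raise ValueError("window out of bounds")
    window = cmap.matrix[i0 - hw : i0 + hw + 1, j0 - hw : j0 + hw + 1]
    score = float(np.nanmean(window))
    if not relative:
        return score
    exp = expected_by_distance(cmap.matrix)
    seps = np.abs(
        (j0 + np.arange(-hw, hw + 1))[None, :] - (i0 + np.arange(-hw, hw + 1))[:, None]
    )
    denom = float(np.nanmean(exp[seps]))
    return score / denom if denom > 0 else float("nan")


def apa_pileup(
    cmap: ContactMap,
    loops_bins: list[tuple[int, int]],
    window_bp: int = 24_000,
    use_balanced: bool = True,
) -> dict:
    """Aggregate peak analysis: average of per-loop observed/expected windows
    (expected from the map-wide per-diagonal mean).  Loops whose window would
    be truncated by the map edge or the diagonal are skipped and counted.

    Returns {"stack": (w, w) array, "n_used": int, "n_skipped": int}.
    """
    if not loops_bins:
        raise ValueError("no loops given")
    mat = cmap.balanced() if (use_balanced and cmap.weights is not None) else cmap.matrix
    n = mat.shape[0]
    hw = int(round(window_bp / 2 / cmap.resolution))
    exp = expected_by_distance(mat)
    acc = np.zeros((2 * hw + 1, 2 * hw + 1))
    used = skipped = 0
    for pair in loops_bins:
        i0, j0 = sorted(int(b) for b in pair)
        if i0 - hw < 0 or j0 + hw >= n or (j0 - i0) <= 2 * hw:
            skipped += 1
            continue
        obs = mat[i0 - hw : i0 + hw + 1, j0 - hw : j0 + hw + 1]
        seps = np.abs((j0 + np.arange(-hw, hw + 1))[None, :] - (i0 + np.arange(-hw, hw + 1))[:, None])
        e = exp[seps]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = obs / e
        acc += np.nan_to_num(ratio, nan=0.0)
        used += 1
    if used == 0:
        raise ValueError("all loops skipped (windows truncated)")
    return {"stack": acc / used, "n_used": used, "n_skipped": skipped}


# ----------------------------------------------------------------------------
# anchor / loop classification


@dataclass
class AnchorAnnotation:
    """Genomic annotation inputs: TSS records, enhancer-mark peaks, CTCF peaks
    with motif orientation and RAD21 peaks.  All 0-based half-open."""

    tss: pd.DataFrame  # chrom, start, end, name
    h3k4me1: pd.DataFrame
    h3k27ac: pd.DataFrame
    ctcf: pd.DataFrame  # with strand
    rad21: pd.DataFrame

    def promoters(self, pad: int = 2000) -> pd.DataFrame:
        """TSS +/- pad."""
        tss_point = (self.tss["start"] + self.tss["end"]) // 2
        return pd.DataFrame(
            {
                "chrom": self.tss["chrom"],
                "start": np.maximum(tss_point - pad, 0),
                "end": tss_point + pad,
                "name": self.tss.get("name", pd.Series(["tss"] * len(self.tss))),
            }
        )

    def enhancers(self) -> pd.DataFrame:
        """Intersection of H3K4me1 and H3K27ac peaks."""
        return _interval_intersection(self.h3k4me1, self.h3k27ac)

    def ctcf_rad21(self) -> pd.DataFrame:
        """Intersection of CTCF and RAD21 peaks (CTCF orientation kept)."""
        return _interval_intersection(self.ctcf, self.rad21, keep_strand=True)


def _interval_intersection(a: pd.DataFrame, b: pd.DataFrame, keep_strand: bool = False) -> pd.DataFrame:
    rows = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        aa = a[a["chrom"] == chrom]
        bb = b[b["chrom"] == chrom]
        for _, ra in aa.iterrows():
            for _, rb in bb.iterrows():
                lo = max(ra["start"], rb["start"])
                hi = min(ra["end"], rb["end"])
                if lo < hi:
                    row = {"chrom": chrom, "start": lo, "end": hi}
                    if keep_strand and "strand" in ra:
                        row["strand"] = ra["strand"]
                    rows.append(row)
    cols = ["chrom", "start", "end"] + (["strand"] if keep_strand else [])
    return pd.DataFrame(rows, columns=cols)


def _overlaps_any(chrom, start, end, features: pd.DataFrame) -> bool:
    if features.empty:
        return False
    f = features[features["chrom"] == chrom]
    return bool(((f["start"] < end) & (f["end"] > start)).any())


def classify_anchors(
    anchors: pd.DataFrame,
    annotation: AnchorAnnotation,
    mode: str = "inclusive",
    pad: int = 1000,
) -> pd.Series:
    """Classify each anchor interval as promoter / enhancer / ctcf / other.

    Anchors (padded by ``pad``) are intersected with promoters (TSS +/- 2 kb),
    enhancers (H3K4me1 AND H3K27ac, non-promoter) and CTCF/RAD21 (both peaks,
    non-promoter, non-enhancer), hierarchically: promoter > enhancer > ctcf.
    ``exclusive`` mode labels anchors that overlap both a CRE (promoter or
    enhancer) and CTCF/RAD21 as ``"dropped"``.
    """
    if mode not in ("inclusive", "exclusive"):
        raise ValueError(f"mode must be inclusive or exclusive, got {mode!r}")
    bad = anchors["end"] <= anchors["start"]
    if bad.any():
        lines = ", ".join(str(i) for i in anchors.index[bad][:5])
        raise ValueError(f"malformed anchor intervals (end <= start) at rows: {lines}")
    proms = annotation.promoters()
    enhs = annotation.enhancers()
    ctcfs = annotation.ctcf_rad21()
    labels = []
    for _, row in anchors.iterrows():
        chrom, lo, hi = row["chrom"], row["start"] - pad, row["end"] + pad
        is_p = _overlaps_any(chrom, lo, hi, proms)
        is_e = _overlaps_any(chrom, lo, hi, enhs)
        is_c = _overlaps_any(chrom, lo, hi, ctcfs)
        if mode == "exclusive" and (is_p or is_e) and is_c:
            labels.append("dropped")
        elif is_p:
            labels.append("promoter")
        elif is_e:
            labels.append("enhancer")
        elif is_c:
            labels.append("ctcf")
        else:
            labels.append("other")
    return pd.Series(labels, index=anchors.index, name="anchor_class")


def _loop_class(c1: str, c2: str) -> str:
    cre = {"promoter": "P", "enhancer": "E"}
    if c1 == "dropped" or c2 == "dropped":
        return "dropped"
    if c1 in cre and c2 in cre:
        pair = sorted([cre[c1], cre[c2]], reverse=True)  # P before E? want P-P, E-P, E-E
        if pair == ["P", "P"]:
            return "P-P"
        if pair == ["P", "E"]:
            return "E-P"
        return "E-E"
    if (c1 in cre and c2 == "ctcf") or (c2 in cre and c1 == "ctcf"):
        return "E/P-CTCF"
    if c1 == "ctcf" and c2 == "ctcf":
        return "CTCF-CTCF"
    return "other"


@dataclass
class LoopTable:
    """BEDPE-like loops with optional anchor/loop classes."""

    loops: pd.DataFrame  # chrom1,start1,end1,chrom2,start2,end2 [,class1,class2,loop_class]
    mode: str = "inclusive"

    def __post_init__(self) -> None:
        df = self.loops
        swap = df["start2"] < df["start1"]
        if swap.any():  # canonical anchor order
            cols1 = ["chrom1", "start1", "end1"]
            cols2 = ["chrom2", "start2", "end2"]
            a = df.loc[swap, cols1].to_numpy()
            df.loc[swap, cols1] = df.loc[swap, cols2].to_numpy()
            df.loc[swap, cols2] = a
        self.loops = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.loops)


def classify_loops(table: LoopTable, annotation: AnchorAnnotation, mode: str = "inclusive") -> LoopTable:
    """Attach anchor and loop classes; exclusive mode drops loops whose
    anchors meet both CRE and CTCF/RAD21 definitions."""
    df = table.loops.copy()
    a1 = df[["chrom1", "start1", "end1"]].rename(columns=lambda c: c[:-1])
    a2 = df[["chrom2", "start2", "end2"]].rename(columns=lambda c: c[:-1])
    c1 = classify_anchors(a1, annotation, mode=mode)
    c2 = classify_anchors(a2, annotation, mode=mode)
    df["class1"], df["class2"] = c1.values, c2.values
    df["loop_class"] = [_loop_class(x, y) for x, y in zip(c1, c2)]
    if mode == "exclusive":
        df = df[df["loop_class"] != "dropped"].reset_index(drop=True)
    return LoopTable(df, mode=mode)


# ----------------------------------------------------------------------------
# compartments


def compartment_call(cmap: ContactMap, orientation_track: np.ndarray) -> dict:
    """Leading eigenvector of the observed/expected correlation matrix,
    oriented so its correlation with ``orientation_track`` (e.g. G+C content)
    is positive; positive bins = A compartment.

    Returns {"eigenvector", "labels" (+1 A / -1 B / 0 masked),
    "transitions" (bin indices where the sign changes), "reliable"}.
    """
    if cmap.weights is None:
        cmap = ice_balance(cmap)
    mat = cmap.balanced()
    n = mat.shape[0]
    orientation_track = np.asarray(orientation_track, dtype=float)
    if len(orientation_track) != n:
        raise ValueError("orientation track must cover all bins")
    mask = np.isfinite(cmap.weights)
    if not mask.any():
        raise ValueError("degenerate map: no unmasked bins")
    sub = mat[np.ix_(mask, mask)]
    exp = expected_by_distance(sub)
    seps = np.abs(np.subtract.outer(np.arange(sub.shape[0]), np.arange(sub.shape[0])))
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = sub / exp[seps]
    oe[~np.isfinite(oe)] = 1.0
    if np.allclose(oe.std(axis=0), 0):
        # featureless (e.g. uniform) map: no compartment structure to call
        n_sub = sub.shape[0]
        labels = np.zeros(n, dtype=int)
        return {
            "eigenvector": np.where(mask, 0.0, np.nan),
            "labels": labels,
            "transitions": np.array([], dtype=int),
            "reliable": False,
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        corr = np.corrcoef(oe)
    corr[~np.isfinite(corr)] = 0.0
    vals, vecs = np.linalg.eigh(corr)
    ev = vecs[:, -1]
    # variance of the correlation structure captured by the leading eigenvalue
    reliable = bool(ev.std() > 1e-8 and vals[-1] > 1.5 * max(vals[-2], 1e-12))
    track_sub = orientation_track[mask]
    cmat = np.corrcoef(ev, track_sub)
    if np.isfinite(cmat[0, 1]) and cmat[0, 1] < 0:
        ev = -ev
    full = np.full(n, np.nan)
    full[mask] = ev
    labels = np.zeros(n, dtype=int)
    labels[np.nan_to_num(full) > 0] = 1
    labels[np.nan_to_num(full) < 0] = -1
    sign = labels[labels != 0]
    idx = np.flatnonzero(labels != 0)
    transitions = idx[1:][np.diff(sign) != 0]
    return {"eigenvector": full, "labels": labels, "transitions": transitions, "reliable": reliable}


def classify_loop_compartments(loops_bins: list[tuple[int, int]], labels: np.ndarray) -> dict:
    """Label each loop intra-A / intra-B / inter by its anchors' compartment
    signs; masked-bin anchors are counted as unassigned."""
    counts = {"intra-A": 0, "intra-B": 0, "inter": 0, "unassigned": 0}
    per_loop = []
    for i, j in loops_bins:
        li, lj = labels[int(i)], labels[int(j)]
        if li == 0 or lj == 0:
            cat = "unassigned"
        elif li == 1 and lj == 1:
            cat = "intra-A"
        elif li == -1 and lj == -1:
            cat = "intra-B"
        else:
            cat = "inter"
        counts[cat] += 1
        per_loop.append(cat)
    total = sum(v for k, v in counts.items() if k != "unassigned")
    fractions = {k: (counts[k] / total if total else 0.0) for k in ("intra-A", "intra-B", "inter")}
    return {"counts": counts, "fractions": fractions, "per_loop": per_loop}
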