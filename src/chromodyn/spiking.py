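"""PCA classifier for transcriptional spiking at mitotic exit.

Many genes transiently exceed their later-G1 steady-state Pol II levels
around anaphase-telophase (AT).  The classifier quantifies mean Pol II ChIP
signal in a 2.5-kb TSS window at five time points (PM, AT, EG1, MG1, LG1),
keeps active genes (signal >= threshold at every time point except PM),
normalizes each gene by its mean over the three G1 time points, and runs PCA
over genes; PC1 captures the AT peak, and genes with positive PC1 scores are
labeled spiking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIME_POINTS = ("PM", "AT", "EG1", "MG1", "LG1")
G1_POINTS = ("EG1", "MG1", "LG1")

__all__ = [
    "TIME_POINTS",
    "PolIIMatrix",
    "SpikingModel",
    "SpikingResult",
    "build_polII_matrix",
    "normalize_and_filter",
    "pca_classify",
]


@dataclass
class PolIIMatrix:
    """Genes x 5 time points of mean Pol II signal in a TSS-centered window."""

    values: pd.DataFrame  # index = gene, columns = TIME_POINTS

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(TIME_POINTS):
            raise ValueError(f"columns must be {TIME_POINTS} in order")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("Pol II signals must be non-negative")


def build_polII_matrix(
    tracks: dict[str, pd.DataFrame],
    tss: pd.DataFrame,
    window: int = 2500,
) -> PolIIMatrix:
    """Mean signal per time point in a ``window``-bp TSS-centered window.

    ``tracks``: time point -> bedGraph-style DataFrame (chrom, start, end,
    value).  ``tss``: chrom, start, end, name (gene), one row per TSS; for
    genes with several TSSs the dominant one (largest summed signal across the
    five time points) is kept.  TSSs with no track coverage are dropped with a
    warning.
    """
    import warnings

    missing = [tp for tp in TIME_POINTS if tp not in tracks]
    if missing:
        raise ValueError(f"missing tracks for time points: {missing}")
    rows = []
    for idx, rec in tss.iterrows():
        point = (rec["start"] + rec["end"]) // 2
        lo, hi = point - window // 2, point + window // 2
        sig = {}
        covered = True
        for tp in TIME_POINTS:
            tr = tracks[tp]
            sel = tr[(tr["chrom"] == rec["chrom"]) & (tr["end"] > lo) & (tr["start"] < hi)]
            if sel.empty:
                covered = False
                break
            # length-weighted mean over the window
            ov = np.minimum(sel["end"], hi) - np.maximum(sel["start"], lo)
            sig[tp] = float((sel["value"] * ov).sum() / (hi - lo))
        if not covered:
            warnings.warn(f"TSS {rec.get('name', idx)} outside track coverage; dropped")
            continue
        rows.append({"gene": rec.get("name", f"gene{idx}"), **sig})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no TSS with track coverage")
    df["_total"] = df[list(TIME_POINTS)].sum(axis=1)
    df = df.sort_values("_total", ascending=False).drop_duplicates("gene").drop(columns="_total")
    df = df.set_index("gene").sort_index()
    return PolIIMatrix(df[list(TIME_POINTS)])


def normalize_and_filter(matrix: PolIIMatrix, active_threshold: float = 0.5) -> PolIIMatrix:
    """Drop genes below ``active_threshold`` at any time point except PM, then
    divide each surviving row by its mean over the three G1 time points."""
    df = matrix.values
    non_pm = [tp for tp in TIME_POINTS if tp != "PM"]
    active = (df[non_pm] >= active_threshold).all(axis=1)
    kept = df[active].copy()
    g1_mean = kept[list(G1_POINTS)].mean(axis=1)
    assert (g1_mean > 0).all(), "G1 mean of an active gene cannot be zero"
    return PolIIMatrix(kept.div(g1_mean, axis=0))


@dataclass
class SpikingResult:
    """Fit output: PC1 scores, labels, explained variance, loadings."""

    scores: pd.Series  # PC1 per gene
    labels: pd.Series  # "spiking" | "nonspiking"
    variance_explained: np.ndarray  # per component, fractions
    loadings: pd.Series  # PC1 loading per time point
    normalized: pd.DataFrame

    @property
    def spiking_fraction(self) -> float:
        return float((self.labels == "spiking").mean())

    def summary(self) -> str:
        lines = [
            "Transcriptional spiking PCA",
            "=" * 40,
            f"genes analyzed        {len(self.scores)}",
            f"spiking (PC1 > 0)     {(self.labels == 'spiking').sum()} "
            f"({100 * self.spiking_fraction:.1f}%)",
            f"PC1 variance explained {100 * self.variance_explained[0]:.1f}%",
            "PC1 loadings: "
            + "  ".join(f"{tp}={v:+.2f}" for tp, v in self.loadings.items()),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pc1": self.scores, "label": self.labels})


class SpikingModel:
    """Spiking classifier as a fit-style model over a Pol II matrix."""

    def __init__(self, matrix: PolIIMatrix, active_threshold: float = 0.5):
        self.raw = matrix
        self.active_threshold = active_threshold

    @classmethod
    def from_tracks(cls, tracks, tss, window: int = 2500, active_threshold: float = 0.5):
        return cls(build_polII_matrix(tracks, tss, window), active_threshold)

    def fit(self) -> SpikingResult:
        norm = normalize_and_filter(self.raw, self.active_threshold)
        return pca_classify(norm)


def pca_classify(normalized: PolIIMatrix) -> SpikingResult:
    """PCA over genes-as-observations of the normalized 5-point profiles.

    Columns are mean-centered (no variable scaling).  PC1 is oriented so that
    its AT loading exceeds its mean G1 loading, making "positive score =
    spiking" deterministic.
    """
    df = normalized.values
    if len(df) < 3:
        raise ValueError("need at least 3 active genes for PCA")
    X = df.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("zero-variance matrix: all profiles identical")
    # SVD-based PCA (deterministic; no scaling of variables)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(len(df) - 1, 1)
    var_frac = var / var.sum()
    pc1 = vt[0]
    at_idx = TIME_POINTS.index("AT")
    g1_idx = [TIME_POINTS.index(tp) for tp in G1_POINTS]
    if pc1[at_idx] - pc1[g1_idx].mean() < 0:
        pc1 = -pc1
    scores = pd.Series(Xc @ pc1, index=df.index, name="pc1")
    labels = pd.Series(
        np.where(scores > 0, "spiking", "nonspiking"), index=df.index, name="label"
    )
    return SpikingResult(
        scores=scores,
        labels=labels,
        variance_explained=var_frac,
        loadings=pd.Series(pc1, index=list(TIME_POINTS)),
        normalized=df,
    )
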