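"""Seeded synthetic-data generators with ground-truth manifests.

Every input the analysis stack consumes can be generated here: BED-like
genomic annotations (TSS, enhancer marks, CTCF/RAD21 peaks with motif
orientation), A/B/C monomer typings for the polymer model, binned contact
maps with power-law distance decay, planted focal loops and planted A/B
checkerboard structure, and Pol II ChIP-like five-time-point series with a
spiking subpopulation.  Each generator is a pure function of its seed and
parameters and returns a manifest from which every planted feature is
recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapstats import AnchorAnnotation, ContactMap
from .polymer import MonomerTyping
from .spiking import TIME_POINTS, PolIIMatrix

__all__ = [
    "SyntheticManifest",
    "gen_annotations",
    "gen_monomer_typing",
    "gen_synthetic_map",
    "gen_polII_series",
]


@dataclass
class SyntheticManifest:
    """Seed, generator parameters and planted ground truth."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")

        with open(path, "w") as fh:
            json.dump(
                {"generator": self.generator, "seed": self.seed, "params": self.params, "truth": self.truth},
                fh,
                indent=2,
                default=_default,
            )


def gen_annotations(
    region_length: int = 2_000_000,
    n_genes: int = 20,
    n_enhancers: int = 30,
    n_ctcf: int = 20,
    cre_ctcf_fraction: float = 0.2,
    chrom: str = "chrS",
    peak_width: int = 400,
    seed: int = 0,
) -> tuple[AnchorAnnotation, SyntheticManifest]:
    """Non-overlapping TSSs, enhancers (coincident H3K4me1 + H3K27ac peaks)
    and CTCF peaks with random motif orientation plus matched RAD21 peaks.
    A ``cre_ctcf_fraction`` of CREs is co-located with a CTCF/RAD21 peak to
    exercise the inclusive/exclusive classification logic.
    """
    rng = np.random.default_rng(seed)
    n_features = n_genes + n_enhancers + n_ctcf
    slot = region_length // max(n_features, 1)
    if slot < 6000:
        raise ValueError(
            f"infeasible density: {n_features} features in {region_length} bp "
            "(need >= 6 kb per feature to keep promoters non-overlapping)"
        )
    # one feature per slot, jittered, so nothing collides
    starts = (np.arange(n_features) * slot + slot // 2
              + rng.integers(-slot // 8, slot // 8 + 1, n_features))
    rng.shuffle(starts)
    tss_pos = np.sort(starts[:n_genes])
    enh_pos = np.sort(starts[n_genes : n_genes + n_enhancers])
    ctcf_pos = np.sort(starts[n_genes + n_enhancers :])

    tss = pd.DataFrame(
        {"chrom": chrom, "start": tss_pos, "end": tss_pos + 1,
         "name": [f"gene{i}" for i in range(n_genes)]}
    )

    def peaks(positions):
        return pd.DataFrame(
            {"chrom": chrom, "start": positions - peak_width // 2, "end": positions + peak_width // 2}
        )

    h3k4me1 = peaks(enh_pos)
    h3k27ac = peaks(enh_pos)
    strands = rng.choice(["+", "-"], size=len(ctcf_pos))
    ctcf = peaks(ctcf_pos)
    ctcf["strand"] = strands
    rad21 = peaks(ctcf_pos)

    # co-locate a fraction of CREs with CTCF/RAD21
    cre_pos = np.concatenate([tss_pos, enh_pos])
    n_co = int(round(cre_ctcf_fraction * len(cre_pos)))
    co_sites = rng.choice(cre_pos, size=n_co, replace=False) if n_co else np.array([], dtype=int)
    if n_co:
        extra = peaks(np.sort(co_sites))
        extra_strand = rng.choice(["+", "-"], size=n_co)
        extra_ctcf = extra.copy()
        extra_ctcf["strand"] = extra_strand
        ctcf = pd.concat([ctcf, extra_ctcf], ignore_index=True).sort_values("start").reset_index(drop=True)
        rad21 = pd.concat([rad21, extra], ignore_index=True).sort_values("start").reset_index(drop=True)

    ann = AnchorAnnotation(tss=tss, h3k4me1=h3k4me1, h3k27ac=h3k27ac, ctcf=ctcf, rad21=rad21)
    manifest = SyntheticManifest(
        "gen_annotations",
        seed,
        params={
            "region_length": region_length, "n_genes": n_genes, "n_enhancers": n_enhancers,
            "n_ctcf": n_ctcf, "cre_ctcf_fraction": cre_ctcf_fraction, "peak_width": peak_width,
        },
        truth={
            "tss_pos": tss_pos, "enhancer_pos": enh_pos, "ctcf_pos": ctcf_pos,
            "ctcf_strands": strands, "cre_ctcf_sites": np.sort(co_sites),
        },
    )
    return ann, manifest


def gen_monomer_typing(
    locus_monomers: int = 3850,
    spacer_monomers: int | None = None,
    copies: int = 8,
    c_anchor_spacing_kb: float = 20.0,
    c_block_monomers: int = 3,
    b_fraction: float = 0.4,
    ab_block_monomers: int = 300,
    sigma_kb: float = 0.5,
    seed: int = 0,
) -> MonomerTyping:
    """A/B/C monomer typing emulating a CRE-dense ~1.9-Mb locus.

    The locus alternates A and B blocks (``ab_block_monomers`` long, a
    ``b_fraction`` of them B) with 3-monomer (1.5-kb) C blocks planted every
    ``c_anchor_spacing_kb`` on average; ``copies`` locus copies are
    intercalated with neutral A-type spacers of the same length (default),
    reproducing the 8 x (3,850 + 3,850) = 61,600-monomer layout at full scale.
    """
    rng = np.random.default_rng(seed)
    if spacer_monomers is None:
        spacer_monomers = locus_monomers
    locus = np.zeros(locus_monomers, dtype=np.int8)
    n_blocks = max(locus_monomers // ab_block_monomers, 1)
    b_blocks = rng.random(n_blocks) < b_fraction
    for k in range(n_blocks):
        if b_blocks[k]:
            locus[k * ab_block_monomers : (k + 1) * ab_block_monomers] = 1
    spacing = max(int(round(c_anchor_spacing_kb / sigma_kb)), c_block_monomers + 2)
    anchors = np.arange(spacing // 2, locus_monomers - c_block_monomers, spacing)
    anchors = anchors + rng.integers(-spacing // 4, spacing // 4 + 1, len(anchors))
    anchors = np.clip(anchors, 0, locus_monomers - c_block_monomers)
    # merge overlapping C blocks if the jitter collides
    anchors = np.unique(anchors)
    keep = [anchors[0]] if len(anchors) else []
    for x in anchors[1:]:
        if x - keep[-1] >= c_block_monomers + 1:
            keep.append(x)
    for x in keep:
        locus[x : x + c_block_monomers] = 2
    spacer = np.zeros(spacer_monomers, dtype=np.int8)
    codes = np.concatenate([np.concatenate([locus, spacer]) for _ in range(copies)])
    layout = {
        "copies": copies,
        "locus_monomers": locus_monomers,
        "spacer_monomers": spacer_monomers,
        "c_anchors_in_locus": [int(x) for x in keep],
        "c_block_monomers": c_block_monomers,
        "sigma_kb": sigma_kb,
        "seed": seed,
    }
    return MonomerTyping(codes, layout)


def gen_synthetic_map(
    n_bins: int = 200,
    resolution: int = 500,
    decay_exponent: float = -1.0,
    base_count: float = 200.0,
    loops: list[dict] | None = None,
    compartment_blocks: np.ndarray | None = None,
    compartment_amplitude: float = 0.3,
    noise: str = "poisson",
    seed: int = 0,
) -> tuple[ContactMap, SyntheticManifest]:
    """Contact map with power-law decay, planted loops and A/B checkerboard.

    expected[i,j] = base * (1 + |i-j|)^decay * checkerboard(i,j) + loop excess,
    with checkerboard(i,j) = 1 + amp for same-label bins and 1 - amp otherwise.
    ``loops``: list of {"i": bin, "j": bin, "excess": counts-per-cell}; the
    excess is added on the single loop cell (and its transpose).
    ``noise``: "poisson" samples counts; "none" returns the expected matrix.
    """
    rng = np.random.default_rng(seed)
    loops = loops or []
    seps = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    expected = base_count * (1.0 + seps) ** decay_exponent
    if compartment_blocks is not None:
        labels = np.asarray(compartment_blocks)
        if len(labels) != n_bins:
            raise ValueError("compartment_blocks must label every bin")
        same = np.equal.outer(labels, labels)
        expected = expected * np.where(same, 1.0 + compartment_amplitude, 1.0 - compartment_amplitude)
    for lp in loops:
        i, j, e = int(lp["i"]), int(lp["j"]), float(lp["excess"])
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise ValueError(f"loop ({i},{j}) outside map of {n_bins} bins")
        if e < 0:
            raise ValueError("loop excess must be >= 0")
        expected[i, j] += e
        if i != j:
            expected[j, i] += e
    if np.any(expected < 0):
        raise ValueError("expected matrix has negative entries")
    if noise == "none":
        mat = expected.copy()
    elif noise == "poisson":
        upper = rng.poisson(np.triu(expected))
        mat = np.triu(upper) + np.triu(upper, k=1).T
        mat = mat.astype(float)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    cmap = ContactMap(mat, resolution=resolution, provenance="synthetic")
    manifest = SyntheticManifest(
        "gen_synthetic_map",
        seed,
        params={
            "n_bins": n_bins, "resolution": resolution, "decay_exponent": decay_exponent,
            "base_count": base_count, "compartment_amplitude": compartment_amplitude, "noise": noise,
        },
        truth={
            "loops": loops,
            "compartment_blocks": (None if compartment_blocks is None else np.asarray(compartment_blocks)),
        },
    )
    return cmap, manifest


def gen_polII_series(
    n_genes: int = 100,
    spiking_fraction: float = 0.38,
    spike_amplitude: float = 2.0,
    noise_cv: float = 0.1,
    pm_level: float = 0.2,
    seed: int = 0,
) -> tuple[PolIIMatrix, SyntheticManifest]:
    """Five-time-point Pol II profiles with a planted spiking subpopulation.

    Nonspiking genes sit at their G1 steady-state level (low PM); spiking
    genes are elevated ``spike_amplitude``-fold at AT (and halfway at EG1)
    over their G1 level.  Multiplicative log-normal noise with the given CV.
    Default planted fraction 0.38 mirrors the observed share of active genes
    that spike at mitotic exit.
    """
    if not 0.0 <= spiking_fraction <= 1.0:
        raise ValueError("spiking_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_spike = int(round(spiking_fraction * n_genes))
    labels = np.array(["spiking"] * n_spike + ["nonspiking"] * (n_genes - n_spike))
    rng.shuffle(labels)
    base = rng.lognormal(mean=0.5, sigma=0.4, size=n_genes)  # per-gene G1 level
    prof = np.empty((n_genes, 5))
    for g in range(n_genes):
        if labels[g] == "spiking":
            shape = np.array([pm_level, spike_amplitude, (1 + spike_amplitude) / 2, 1.0, 1.0])
        else:
            shape = np.array([pm_level, 1.0, 1.0, 1.0, 1.0])
        prof[g] = base[g] * shape
    sigma_ln = np.sqrt(np.log(1.0 + noise_cv**2))
    noise = rng.lognormal(mean=-sigma_ln**2 / 2, sigma=sigma_ln, size=prof.shape)
    values = pd.DataFrame(
        prof * noise, columns=list(TIME_POINTS),
        index=[f"gene{i}" for i in range(n_genes)],
    )
    matrix = PolIIMatrix(values)
    manifest = SyntheticManifest(
        "gen_polII_series",
        seed,
        params={
            "n_genes": n_genes, "spiking_fraction": spiking_fraction,
            "spike_amplitude": spike_amplitude, "noise_cv": noise_cv, "pm_level": pm_level,
        },
        truth={"labels": {f"gene{i}": labels[i] for i in range(n_genes)}},
    )
    return matrix, manifest
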