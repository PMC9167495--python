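"""Phospho-site filtering, window extraction, and consensus-logo matrices.

Predicted phosphorylation sites (NetPhos-style score tables) are filtered to
reliable tyrosine consensuses (score strictly greater than 0.5 by default),
fixed-width residue windows are cut around each site, and per-position
residue frequencies and information content are computed.

Information content per position: ``R_i = log2(20) - H_i - e_n`` with
``H_i = -sum_a f(a,i) log2 f(a,i)`` and the small-sample correction
``e_n = (s - 1) / (2 n ln 2)``, ``s = 20`` residue types and ``n`` sequences
(Schneider correction; applied when requested, clipped at zero).  The
probability rendering reports the frequencies; the entropy rendering reports
letter heights ``f(a,i) * R_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .patterns import AMINO_ACIDS

PAD = "-"  # end-of-protein padding; excluded from counts


@dataclass(frozen=True)
class PhosphoSite:
    protein_id: str
    position: int  # 1-based residue index
    residue: str
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"{self.protein_id}:{self.position}: score {self.score} outside [0,1]")


@dataclass
class LogoMatrix:
    freqs: pd.DataFrame  # positions x residues, rows sum to 1 (NaN row if no data)
    info_bits: np.ndarray  # R_i per position (NaN where undefined)
    heights: pd.DataFrame  # rendering-dependent letter heights
    n: int  # number of sequences
    e_n: float
    rendering: str


def load_phospho_table(
    path: str | Path, sequences: dict[str, str] | None = None
) -> list[PhosphoSite]:
    """Read a NetPhos-style TSV (protein_id, position, residue, score); when
    ``sequences`` is given, each site's residue is validated against it."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_id", "position", "residue", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phospho table lacks columns: {sorted(missing)}")
    sites = [
        PhosphoSite(str(r.protein_id), int(r.position), str(r.residue), float(r.score))
        for r in df.itertuples(index=False)
    ]
    if sequences is not None:
        for s in sites:
            seq = sequences.get(s.protein_id)
            if seq is None:
                raise ValueError(f"unknown protein {s.protein_id!r} in phospho table")
            if not 1 <= s.position <= len(seq) or seq[s.position - 1] != s.residue:
                raise ValueError(
                    f"{s.protein_id}:{s.position}: residue {s.residue!r} does not match sequence"
                )
    return sites


def select_phospho_sites(
    table: list[PhosphoSite],
    threshold: float = 0.5,
    residue_filter: str = "Y",
) -> list[PhosphoSite]:
    """Reliable sites: residue equals the filter and score strictly above the
    threshold; duplicates per (protein, position) keep the maximal score."""
    best: dict[tuple[str, int], PhosphoSite] = {}
    for site in table:
        if site.residue != residue_filter or not site.score > threshold:
            continue
        key = (site.protein_id, site.position)
        if key not in best or site.score > best[key].score:
            best[key] = site
    return [best[k] for k in sorted(best)]


def extract_windows(
    sequences: dict[str, str],
    sites: list[PhosphoSite],
    halfwidth: int = 5,
) -> list[str]:
    """Fixed-width residue windows ``[pos - halfwidth, pos + halfwidth]``,
    padded with :data:`PAD` past the protein ends."""
    windows = []
    for site in sites:
        seq = sequences.get(site.protein_id)
        if seq is None:
            raise ValueError(f"unknown protein {site.protein_id!r}")
        if not 1 <= site.position <= len(seq):
            raise ValueError(f"{site.protein_id}: position {site.position} outside sequence")
        chars = []
        for offset in range(-halfwidth, halfwidth + 1):
            idx = site.position - 1 + offset
            chars.append(seq[idx] if 0 <= idx < len(seq) else PAD)
        windows.append("".join(chars))
    return windows


def logo_matrix(
    windows: list[str],
    rendering: str = "probability",
    small_sample_correction: bool | None = None,
) -> LogoMatrix:
    """Residue frequencies and information content of aligned windows.

    ``small_sample_correction`` defaults to True for the entropy rendering
    and False for the probability rendering.  Pad symbols are excluded from
    per-position counts; a position with zero non-pad observations gets NaN
    frequencies and NaN information content.
    """
    if not windows:
        raise ValueError("at least one window required")
    if rendering not in ("probability", "entropy"):
        raise ValueError(f"unknown rendering {rendering!r}")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows differ in width")
    if small_sample_correction is None:
        small_sample_correction = rendering == "entropy"
    n = len(windows)
    s = len(AMINO_ACIDS)
    e_n = (s - 1) / (2 * n * math.log(2)) if small_sample_correction else 0.0
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((width, s))
    for w in windows:
        for pos, ch in enumerate(w):
            idx = aa_index.get(ch)
            if idx is not None:
                counts[pos, idx] += 1
    totals = counts.sum(axis=1)
    freqs = np.full_like(counts, np.nan)
    info = np.full(width, np.nan)
    for pos in range(width):
        if totals[pos] == 0:
            continue
        f = counts[pos] / totals[pos]
        freqs[pos] = f
        nz = f[f > 0]
        H = -(nz * np.log2(nz)).sum()
        info[pos] = max(0.0, math.log2(s) - H - e_n)
    freq_df = pd.DataFrame(freqs, columns=list(AMINO_ACIDS))
    freq_df.index = range(1, width + 1)
    freq_df.index.name = "position"
    if rendering == "probability":
        heights = freq_df.copy()
    else:
        heights = freq_df.mul(pd.Series(info, index=freq_df.index), axis=0)
    return LogoMatrix(
        freqs=freq_df,
        info_bits=info,
        heights=heights,
        n=n,
        e_n=e_n,
        rendering=rendering,
    )


def plot_logo(matrix: LogoMatrix, path: str | Path, title: str = "") -> None:
    """Minimal stacked-letter-height bar rendering via matplotlib (optional
    output; the matrices are the primary artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(matrix.heights)), 3))
    bottom = np.zeros(len(matrix.heights))
    positions = np.asarray(matrix.heights.index)
    for aa in matrix.heights.columns:
        vals = matrix.heights[aa].fillna(0.0).to_numpy()
        ax.bar(positions, vals, bottom=bottom, width=0.8, label=aa)
        bottom += vals
    ax.set_xlabel("position")
    ax.set_ylabel("bits" if matrix.rendering == "entropy" else "probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "LogoMatrix",
    "PAD",
    "PhosphoSite",
    "extract_windows",
    "load_phospho_table",
    "logo_matrix",
    "plot_logo",
    "select_phospho_sites",
]
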