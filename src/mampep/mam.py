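"""Motif Activation Map: per-site contribution scores and motif summaries.

Because the pooled heads are linear, the trained weights can be pushed back
onto the convolutional feature maps: the contribution of site k is

    S_k = sum_i m_i * sum_j W_ij * F_ijk

with F_ijk the post-activation feature of filter j at site k in level i,
m_i the fusion weight of level i and W_ij that level's pooling-head weight.
S intentionally omits the 1/L pooling factor — a uniform positive scaling
under "same" padding — which buys the exact identity

    sigmoid(mean_k S_k) = predicted probability,

so the attribution provably decomposes the prediction. sign(S_k) marks
motif-candidate sites (negative-contribution sites cannot be motifs), and a
site is called important when its mean score over a peptide set is strictly
positive, the same reading rule used for the boxplot export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA_ALPHABET, AA_INDEX, encode
from .network import Ensemble, MhcCnn
from .peptide_io import Dataset, PeptideRecord

__all__ = [
    "SiteScoreMatrix", "site_scores", "site_scores_ensemble", "motif_mask",
    "site_summary", "position_frequency_matrix", "export_views",
]


@dataclass
class SiteScoreMatrix:
    """Peptides x positions matrix of contribution scores S_k."""

    scores: np.ndarray          # (n_peptides, L)
    peptides: list[str]

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=np.float64))
        if self.scores.shape[0] != len(self.peptides):
            raise ValueError("row count must match number of peptides")

    @property
    def length(self) -> int:
        return self.scores.shape[1]

    def __len__(self) -> int:
        return self.scores.shape[0]


def _scores_batch(model: MhcCnn, idx: np.ndarray) -> np.ndarray:
    """S for a uniform-length index batch, shape (B, L)."""
    acts, _ = model._activations(idx)
    s = np.zeros(idx.shape, dtype=np.float64)
    for i, a in enumerate(acts):                    # a: (B, L, F_i)
        s += model.fusion_w[i] * (a @ model.gap_w[i])
    return s


def site_scores(model: MhcCnn, peptide) -> np.ndarray:
    """Per-site contribution vector S of one peptide (dropout off).

    Satisfies ``sigmoid(mean(S)) == model probability`` to float precision.
    """
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else str(peptide)
    return _scores_batch(model, encode(seq)[None, :])[0]


def site_scores_ensemble(ensemble: Ensemble, peptides) -> SiteScoreMatrix:
    """Member-averaged site scores for a uniform-length peptide collection."""
    if isinstance(peptides, Dataset):
        seqs = peptides.sequences()
    else:
        seqs = [p.sequence if isinstance(p, PeptideRecord) else str(p) for p in peptides]
    if not seqs:
        raise ValueError("empty peptide collection")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"mixed peptide lengths {sorted(lengths)} in one matrix request")
    idx = np.stack([encode(s) for s in seqs])
    acc = np.zeros(idx.shape, dtype=np.float64)
    for m in ensemble.members:
        acc += _scores_batch(m, idx)
    return SiteScoreMatrix(scores=acc / len(ensemble.members), peptides=seqs)


def motif_mask(scores: np.ndarray) -> np.ndarray:
    """Elementwise sign of the score vector; +1 sites are motif candidates."""
    return np.sign(np.asarray(scores, dtype=np.float64)).astype(np.int64)


def site_summary(matrix: SiteScoreMatrix) -> pd.DataFrame:
    """Per-site distribution statistics (boxplot source).

    A site is flagged ``important`` iff its mean score is strictly positive.
    Sites are reported 1-based.
    """
    if len(matrix) == 0:
        raise ValueError("empty score matrix")
    s = matrix.scores
    return pd.DataFrame({
        "site": np.arange(1, matrix.length + 1),
        "mean": s.mean(axis=0),
        "median": np.median(s, axis=0),
        "q1": np.percentile(s, 25, axis=0),
        "q3": np.percentile(s, 75, axis=0),
        "min": s.min(axis=0),
        "max": s.max(axis=0),
        "important": s.mean(axis=0) > 0.0,
    })


def position_frequency_matrix(peptides) -> pd.DataFrame:
    """Residue frequencies per site over equal-length peptides.

    Returns an L x 20 frame (rows = 1-based sites, columns = alphabet); each
    row sums to 1.
    """
    if isinstance(peptides, Dataset):
        seqs = peptides.sequences()
    else:
        seqs = [p.sequence if isinstance(p, PeptideRecord) else str(p) for p in peptides]
    if not seqs:
        raise ValueError("empty peptide collection")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"mixed peptide lengths {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((L, len(AA_ALPHABET)))
    for s in seqs:
        for k, ch in enumerate(s):
            counts[k, AA_INDEX[ch]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freqs, index=pd.RangeIndex(1, L + 1, name="site"),
                        columns=list(AA_ALPHABET))


def export_views(matrix: SiteScoreMatrix, pfm: pd.DataFrame, out_dir,
                 normalize_heatmap: bool = False, render: bool = False) -> dict[str, Path]:
    """Write heatmap/boxplot/logo source artifacts to ``out_dir``.

    Emits ``heatmap.tsv`` (peptides x sites score table, raw by default,
    optionally row min-max normalized), ``boxplot.tsv`` (per-site statistics)
    and ``pfm.tsv`` (tab-separated position frequency matrix, one row per
    site with 20 labeled columns, consumable by standard logo tools).
    ``render=True`` additionally draws PNG figures with matplotlib.
    Re-export of identical inputs is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = matrix.scores
    if normalize_heatmap:
        lo = scores.min(axis=1, keepdims=True)
        span = scores.max(axis=1, keepdims=True) - lo
        span[span == 0.0] = 1.0
        scores = (scores - lo) / span
    heat = pd.DataFrame(
        scores, index=pd.Index(matrix.peptides, name="peptide"),
        columns=[f"site_{k}" for k in range(1, matrix.length + 1)],
    )
    paths = {
        "heatmap": out_dir / "heatmap.tsv",
        "boxplot": out_dir / "boxplot.tsv",
        "pfm": out_dir / "pfm.tsv",
    }
    heat.to_csv(paths["heatmap"], sep="\t", float_format="%.6g", lineterminator="\n")
    site_summary(matrix).to_csv(paths["boxplot"], sep="\t", index=False,
                                float_format="%.6g", lineterminator="\n")
    pfm.to_csv(paths["pfm"], sep="\t", float_format="%.6g", lineterminator="\n")
    if render:
        paths.update(_render_views(matrix, pfm, out_dir))
    return paths


def _render_views(matrix: SiteScoreMatrix, pfm: pd.DataFrame, out_dir: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sites = np.arange(1, matrix.length + 1)
    out = {}

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(matrix.scores, aspect="auto", cmap="viridis")
    ax.set_xlabel("site")
    ax.set_ylabel("peptide")
    ax.set_xticks(sites - 1, sites)
    fig.colorbar(im, ax=ax, label="contribution S")
    out["heatmap_png"] = out_dir / "heatmap.png"
    fig.savefig(out["heatmap_png"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([matrix.scores[:, k] for k in range(matrix.length)], positions=sites)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("site")
    ax.set_ylabel("contribution S")
    out["boxplot_png"] = out_dir / "boxplot.png"
    fig.savefig(out["boxplot_png"], dpi=120)
    plt.close(fig)

    # simple stacked-frequency logo (letters scaled by per-site frequency)
    fig, ax = plt.subplots(figsize=(6, 3))
    bottom = np.zeros(matrix.length)
    order = np.argsort(pfm.to_numpy(), axis=1)
    for rank in range(pfm.shape[1]):
        heights = np.take_along_axis(pfm.to_numpy(), order[:, rank:rank + 1], axis=1)[:, 0]
        ax.bar(sites, heights, bottom=bottom, width=0.8)
        bottom += heights
    ax.set_xlabel("site")
    ax.set_ylabel("frequency")
    ax.set_xticks(sites)
    out["logo_png"] = out_dir / "logo.png"
    fig.savefig(out["logo_png"], dpi=120)
    plt.close(fig)
    return out
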