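"""Group-level bodily maps: mass-univariate pixel t-tests with FDR control.

For each emotion, the subjects' signed maps (activation minus deactivation)
are tested pixel by pixel against zero with one-sample t-tests; the
resulting p-values are corrected across all in-silhouette pixels of that
emotion's map by the Benjamini-Hochberg step-up procedure at alpha = 0.05,
and t-values of surviving pixels are rendered on a diverging red (activation)
/ blue (deactivation) scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BodyMask, MapCollection
from .preprocess import combine_polarity

__all__ = ["TMap", "pixelwise_t", "bh_fdr", "render_tmap", "group_tmaps"]


@dataclass(frozen=True)
class TMap:
    """Pixel-wise t / p grids for one emotion, with an FDR significance mask."""

    emotion: str
    t_grid: np.ndarray
    p_grid: np.ndarray
    sig_grid: np.ndarray
    df: int
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_grid.shape == self.p_grid.shape == self.sig_grid.shape):
            raise ValueError("t/p/sig grids must share dimensions")
        if self.df < 1:
            raise ValueError("need at least 2 subjects (df >= 1)")


def pixelwise_t(signed_maps: np.ndarray, mask: BodyMask, emotion: str = "") -> TMap:
    """One-sample t vs 0 at every in-silhouette pixel.

    ``signed_maps`` is a (n_subjects, H, W) stack of signed maps.  Pixels
    where every subject reports 0 (zero variance, zero mean — background
    and never-painted skin) get t = 0, p = 1 so they are non-discoveries by
    construction rather than undefined; zero-variance pixels with a nonzero
    mean get an infinite t and p = 0.  The returned ``sig_grid`` is all
    False; apply FDR with :func:`bh_fdr` (or use :func:`group_tmaps`).
    """
    signed_maps = np.asarray(signed_maps, dtype=float)
    if signed_maps.ndim != 3 or signed_maps.shape[1:] != mask.shape:
        raise ValueError("signed_maps must be a (n, H, W) stack matching the mask")
    n = signed_maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a t-test")
    body = mask.body
    vals = signed_maps[:, body]  # (n, n_body)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t[(sd == 0) & (mean == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[np.isinf(t)] = 0.0

    t_grid = np.zeros(mask.shape)
    p_grid = np.ones(mask.shape)
    t_grid[body] = t
    p_grid[body] = p
    return TMap(emotion, t_grid, p_grid, np.zeros(mask.shape, dtype=bool), df=n - 1)


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    reject, *_ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(p.shape)


def apply_fdr(tmap: TMap, mask: BodyMask, alpha: float = 0.05) -> TMap:
    """FDR-correct one emotion's map over its in-silhouette pixels only.

    The correction family is the single emotion's silhouette: corrections
    are per generated map, and background pixels (p = 1 placeholders by
    construction) are kept out of the family.
    """
    body = mask.body
    sig = np.zeros(mask.shape, dtype=bool)
    sig[body] = bh_fdr(tmap.p_grid[body], alpha)
    return TMap(tmap.emotion, tmap.t_grid, tmap.p_grid, sig, tmap.df, alpha)


def group_tmaps(collection: MapCollection, alpha: float = 0.05,
                emotions: list[str] | None = None) -> dict[str, TMap]:
    """Per-emotion FDR-corrected group t-maps from a map collection.

    Only subjects with both polarity maps present for an emotion enter that
    emotion's stack.
    """
    from .core import EMOTIONS

    out: dict[str, TMap] = {}
    for emotion in emotions or EMOTIONS:
        stack = []
        for sid in collection.subject_ids:
            try:
                act, deact = collection.pair(sid, emotion)
            except KeyError:
                continue
            stack.append(combine_polarity(act, deact))
        if len(stack) < 2:
            raise ValueError(f"fewer than 2 complete map pairs for emotion {emotion!r}")
        tmap = pixelwise_t(np.stack(stack), collection.mask, emotion)
        out[emotion] = apply_fdr(tmap, collection.mask, alpha)
    return out


def render_tmap(tmap: TMap, mask: BodyMask, out: str | Path) -> Path:
    """Render a t-map: significant pixels on a symmetric red/blue scale.

    Warm colors mark bodily activation (positive t), cold colors
    deactivation (negative t); non-significant and background pixels stay
    neutral.  The color scale is symmetric about zero and a color bar shows
    the t-statistic range.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.where(tmap.sig_grid, tmap.t_grid, np.nan)
    vmax = np.nanmax(np.abs(shown)) if np.any(tmap.sig_grid) else 1.0
    fig, ax = plt.subplots(figsize=(3, 6))
    ax.imshow(mask.body, cmap="gray_r", alpha=0.15)
    im = ax.imshow(shown, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_title(tmap.emotion)
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.7, label="t")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out


def save_tmap_grids(tmap: TMap, out_dir: str | Path) -> None:
    """Write t / p / sig grids as delimited text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / f"{tmap.emotion}_t.txt", tmap.t_grid, fmt="%.6g")
    np.savetxt(out_dir / f"{tmap.emotion}_p.txt", tmap.p_grid, fmt="%.6g")
    np.savetxt(out_dir / f"{tmap.emotion}_sig.txt", tmap.sig_grid.astype(int), fmt="%d")
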