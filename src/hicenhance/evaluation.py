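"""Evaluation metrics for contact-map enhancement and single-cell recovery.

Two metric families:

* image-similarity metrics on scaled maps or tiles — SSIM and PSNR;
* Hi-C reproducibility scores — a smoothed random-walk concordance
  (GenomeDISCO-style) and a stratum-adjusted correlation coefficient
  (HiCRep-style SCC);

plus the single-cell recovery pipeline: PCA embedding of per-cell
contact vectors, Leiden community detection on the k-NN graph, and the
adjusted Rand index against ground-truth cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d, uniform_filter

__all__ = [
    "ssim",
    "psnr",
    "genomedisco",
    "hicrep_scc",
    "MetricReport",
    "compare_maps",
    "embed_cells",
    "leiden_cluster",
    "ari",
]


def _as2d(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {a.shape}")
    return a


def _pair2d(x, y) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as2d(x), _as2d(y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


# ---------------------------------------------------------------------------
# image metrics
# ---------------------------------------------------------------------------


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    k = np.exp(-(r**2) / (2.0 * sigma**2))
    return k / k.sum()


def ssim(
    x,
    y,
    data_range: float = 1.0,
    k1: float = 0.01,
    k2: float = 0.03,
    win_size: int = 11,
    sigma: float = 1.5,
    gaussian: bool = True,
    constants: tuple[float, float] | None = None,
) -> float:
    """Mean structural similarity between two equally shaped 2-D maps.

    Local means/variances use an 11-tap Gaussian window (sigma = 1.5) by
    default; ``gaussian=False`` switches to a uniform window.  Stability
    constants are ``C1 = (k1 * L)^2`` and ``C2 = (k2 * L)^2`` with ``L``
    the data range; pass ``constants=(C1, C2)`` to override them with
    literal values.
    """
    a, b = _pair2d(x, y)
    if constants is not None:
        c1, c2 = float(constants[0]), float(constants[1])
    else:
        c1 = (k1 * data_range) ** 2
        c2 = (k2 * data_range) ** 2
    if gaussian:
        ker = _gaussian_kernel(win_size, sigma)

        def filt(m):
            return correlate1d(
                correlate1d(m, ker, axis=0, mode="reflect"), ker, axis=1, mode="reflect"
            )

    else:

        def filt(m):
            return uniform_filter(m, size=win_size, mode="reflect")

    mu_a, mu_b = filt(a), filt(b)
    mu_aa, mu_bb, mu_ab = filt(a * a), filt(b * b), filt(a * b)
    var_a = mu_aa - mu_a**2
    var_b = mu_bb - mu_b**2
    cov = mu_ab - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def psnr(x, y, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical inputs."""
    a, b = _pair2d(x, y)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


# ---------------------------------------------------------------------------
# Hi-C reproducibility scores
# ---------------------------------------------------------------------------


def _transition(m: np.ndarray) -> np.ndarray:
    """Row-stochastic normalization; all-zero rows are left at zero."""
    rows = m.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(rows > 0, m / rows, 0.0)
    return p


def genomedisco(x, y, t: int = 3) -> float:
    """Concordance of t-step random walks on the two contact graphs.

    Each map is symmetrized, converted to a row-stochastic transition
    matrix, raised to the t-th power, and rescaled to unit total mass;
    the score is ``1 - ||P_x - P_y||_1 / 2``, in [0, 1] with 1 for
    identical smoothed maps.
    """
    a, b = _pair2d(x, y)
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    scores = []
    for m in (a, b):
        m = np.maximum((m + m.T) / 2.0, 0.0)
        p = _transition(m)
        pt = np.linalg.matrix_power(p, t)
        tot = pt.sum()
        if tot > 0:
            pt = pt / tot
        scores.append(pt)
    return float(1.0 - 0.5 * np.abs(scores[0] - scores[1]).sum())


def _mean_filter(m: np.ndarray, h: int) -> np.ndarray:
    if h == 0:
        return m
    return uniform_filter(m, size=2 * h + 1, mode="constant", cval=0.0)


def hicrep_scc(
    x,
    y,
    h: int = 1,
    max_dist_bins: int | None = None,
) -> float:
    """Stratum-adjusted correlation coefficient between two contact maps.

    Both maps are smoothed with a (2h+1) x (2h+1) mean filter (``h=0``
    disables smoothing), split into diagonal strata by genomic distance
    (up to ``max_dist_bins`` diagonals; all by default), and per-stratum
    Pearson correlations ``r_d`` are combined with weights
    ``w_d = N_d * sd(x_d) * sd(y_d)``:
    ``SCC = sum(w_d r_d) / sum(w_d)``.

    Strata with fewer than two entries or zero variance in either map
    carry zero weight.  Returns NaN if every stratum is degenerate.
    """
    a, b = _pair2d(x, y)
    n = a.shape[0]
    a, b = _mean_filter(a, h), _mean_filter(b, h)
    dmax = n - 1 if max_dist_bins is None else min(max_dist_bins, n - 1)
    num = 0.0
    den = 0.0
    for d in range(dmax + 1):
        xd = np.diagonal(a, offset=d)
        yd = np.diagonal(b, offset=d)
        nd = xd.size
        if nd < 2:
            continue
        sx = float(np.std(xd))
        sy = float(np.std(yd))
        if sx == 0.0 or sy == 0.0:
            continue
        r = float(np.corrcoef(xd, yd)[0, 1])
        w = nd * sx * sy
        num += w * r
        den += w
    if den == 0.0:
        warnings.warn("all diagonal strata degenerate; SCC undefined")
        return float("nan")
    return float(num / den)


@dataclass
class MetricReport:
    """Bundle of per-map-pair scores with a flat-dict view for logging."""

    ssim: float
    psnr: float
    genomedisco: float
    scc: float
    extra: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {
            "ssim": self.ssim,
            "psnr": self.psnr,
            "genomedisco": self.genomedisco,
            "scc": self.scc,
        }
        d.update(self.extra)
        return d


def compare_maps(
    x,
    y,
    data_range: float = 1.0,
    t: int = 3,
    h: int = 1,
    max_dist_bins: int | None = None,
) -> MetricReport:
    """All four metrics for one (candidate, reference) map pair."""
    return MetricReport(
        ssim=ssim(x, y, data_range=data_range),
        psnr=psnr(x, y, data_range=data_range),
        genomedisco=genomedisco(x, y, t=t),
        scc=hicrep_scc(x, y, h=h, max_dist_bins=max_dist_bins),
    )


# ---------------------------------------------------------------------------
# single-cell recovery
# ---------------------------------------------------------------------------


def _cell_features(maps_per_cell: list[dict[str, np.ndarray]]) -> np.ndarray:
    """Stack per-cell upper-triangle vectors over sorted chromosome names."""
    if not maps_per_cell:
        raise ValueError("no cells provided")
    chroms = sorted(maps_per_cell[0].keys())
    rows = []
    for maps in maps_per_cell:
        if sorted(maps.keys()) != chroms:
            raise ValueError("cells disagree on chromosome sets")
        parts = []
        for c in chroms:
            m = np.asarray(maps[c], dtype=np.float64)
            iu = np.triu_indices(m.shape[0])
            parts.append(m[iu])
        rows.append(np.concatenate(parts))
    return np.asarray(rows)


def embed_cells(
    cells,
    n_components: int = 40,
    log1p: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """PCA embedding of per-cell contact vectors.

    ``cells`` is either a 2-D (n_cells, n_features) array or a list of
    per-cell ``{chrom: matrix}`` dicts, flattened to upper-triangle
    vectors.  Features are optionally log1p-transformed and centred;
    the top ``n_components`` principal components are returned
    (capped at the matrix rank).
    """
    from sklearn.decomposition import PCA

    if isinstance(cells, np.ndarray):
        feats = np.asarray(cells, dtype=np.float64)
        if feats.ndim != 2:
            raise ValueError(f"expected 2-D feature array, got {feats.shape}")
    else:
        feats = _cell_features(list(cells))
    if log1p:
        feats = np.log1p(np.maximum(feats, 0.0))
    k = min(n_components, feats.shape[0] - 1, feats.shape[1])
    if k < 1:
        raise ValueError("need at least 2 cells and 1 feature for PCA")
    pca = PCA(n_components=k, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(feats)


def leiden_cluster(
    embedding: np.ndarray,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a k-NN graph of the embedding."""
    import anndata
    import scanpy as sc

    emb = np.asarray(embedding, dtype=np.float64)
    if emb.ndim != 2:
        raise ValueError(f"expected 2-D embedding, got {emb.shape}")
    n_neighbors = min(n_neighbors, emb.shape[0] - 1)
    ad = anndata.AnnData(X=emb.astype(np.float32))
    ad.obsm["X_emb"] = emb
    sc.pp.neighbors(ad, n_neighbors=n_neighbors, use_rep="X_emb", random_state=seed)
    sc.tl.leiden(
        ad,
        resolution=resolution,
        random_state=seed,
        key_added="leiden",
        flavor="leidenalg",
    )
    return ad.obs["leiden"].to_numpy().astype(str)


def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand index between two labelings."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(labels_true), list(labels_pred)))
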