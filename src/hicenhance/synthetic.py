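"""Synthetic chromosomes and single-cell populations for end-to-end testing.

The generator emulates the structure the enhancement model assumes:
a power-law distance decay, TADs (high-contrast squares on the diagonal),
focal loop peaks (corner dots), Poisson-sampled bulk counts, and
ultra-sparse multinomial single cells with cell-type-specific TAD layouts,
library (batch) labels and synthesized QC statistics.

It is test scaffolding in the sense that QC fields are synthesized (no
reads exist), but the count models are the ones under which binomial
down-sampling is exactly depth reduction (Poisson thinning).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ContactMap

__all__ = [
    "SyntheticSpec",
    "CellPopulationSpec",
    "intensity_matrix",
    "sample_bulk",
    "sample_cells",
    "ground_truth",
]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic chromosome.

    ``tads`` are ``(start_bin, end_bin, boost)`` half-open intervals whose
    interior square is multiplied by ``boost``; ``loops`` are
    ``(bin_i, bin_j, boost, width_bins)`` focal peaks with a Gaussian
    taper.  ``depth`` is the expected total read-pair count over the
    upper triangle (diagonal included).
    """

    n_bins: int = 200
    alpha: float = 1.0
    tads: Sequence[tuple[int, int, float]] = ()
    loops: Sequence[tuple[int, int, float, int]] = ()
    depth: float = 2e6
    seed: int = 0
    chrom: str = "chrS"
    bin_size: int = 10_000

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for s, e, b in self.tads:
            if not (0 <= s < e <= self.n_bins):
                raise ValueError(f"TAD ({s}, {e}) outside [0, {self.n_bins})")
            if b < 1:
                raise ValueError("TAD boost must be >= 1")
        for i, j, b, w in self.loops:
            if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
                raise ValueError(f"loop anchor ({i}, {j}) out of bounds")
            if b < 1 or w < 0:
                raise ValueError("loop boost must be >= 1 and width >= 0")


@dataclass
class CellPopulationSpec:
    """Recipe for a multi-type single-cell population.

    One :class:`SyntheticSpec` per cell type (differing TAD layouts);
    cells draw a depth uniformly from ``per_cell_depth`` and sample that
    many contacts from their type's intensity, after per-library
    multiplicative log-normal noise of sd ``batch_effect``.
    ``qc_fail_fraction`` of cells are deliberately given values failing
    each QC filter so the filtering stage is exercised.
    """

    type_specs: Sequence[SyntheticSpec]
    cells_per_type: int = 50
    per_cell_depth: tuple[int, int] = (1000, 5000)
    batch_labels: Sequence[str] = ("lib1", "lib2")
    batch_effect: float = 0.0
    qc_fail_fraction: float = 0.0
    seed: int = 0

    @property
    def n_types(self) -> int:
        return len(self.type_specs)

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("need at least one cell type")
        if self.per_cell_depth[0] < 1:
            raise ValueError("per_cell_depth minimum must be >= 1")
        if self.batch_effect < 0:
            raise ValueError("batch_effect must be >= 0")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ValueError("qc_fail_fraction must be in [0, 1)")


def _loop_kernel(n: int, i0: int, j0: int, boost: float, width: int) -> np.ndarray:
    """Multiplicative Gaussian bump of size (2*width+1)^2 centred on (i0, j0)."""
    factor = np.ones((n, n))
    sigma = max(width, 1) / 2.0
    lo_i, hi_i = max(0, i0 - width), min(n, i0 + width + 1)
    lo_j, hi_j = max(0, j0 - width), min(n, j0 + width + 1)
    ii = np.arange(lo_i, hi_i)[:, None] - i0
    jj = np.arange(lo_j, hi_j)[None, :] - j0
    bump = 1.0 + (boost - 1.0) * np.exp(-(ii**2 + jj**2) / (2.0 * sigma**2))
    factor[lo_i:hi_i, lo_j:hi_j] = bump
    return factor


def intensity_matrix(spec: SyntheticSpec) -> ContactMap:
    """Expected-count matrix: distance decay times TAD and loop boosts.

    ``lam[i, j] = s * (1 + |i - j|)**(-alpha) * prod(tad boosts) *
    prod(loop boosts)`` with the global factor ``s`` chosen so the
    upper-triangle total equals ``spec.depth``.  Strictly positive and
    symmetric.
    """
    n = spec.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    lam = (1.0 + d).astype(np.float64) ** (-spec.alpha)
    for s0, e0, b in spec.tads:
        lam[s0:e0, s0:e0] *= b
    for i0, j0, b, w in spec.loops:
        lam *= _loop_kernel(n, i0, j0, b, w)
        if i0 != j0:
            lam *= _loop_kernel(n, j0, i0, b, w)
    lam = (lam + lam.T) / 2.0
    total = np.triu(lam).sum()
    lam *= spec.depth / total
    return ContactMap(
        chrom=spec.chrom, bin_size=spec.bin_size, matrix=lam, state="raw_counts"
    )


def sample_bulk(spec: SyntheticSpec) -> ContactMap:
    """Poisson-sample a bulk map from the intensity matrix (seeded)."""
    lam = intensity_matrix(spec).matrix
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(lam[iu, ju])
    m = np.zeros((n, n), dtype=np.float64)
    m[iu, ju] = counts
    m[ju, iu] = counts
    return ContactMap(
        chrom=spec.chrom, bin_size=spec.bin_size, matrix=m, state="raw_counts"
    )


@dataclass
class SyntheticCell:
    """One simulated cell: its map, labels and synthesized QC statistics."""

    cell_id: str
    cell_type: str
    library: str
    cmap: ContactMap
    unique_reads: int
    intra_inter_ratio: float
    uniq_map_frac: float


def sample_cells(pop: CellPopulationSpec) -> list[SyntheticCell]:
    """Draw a seeded population of sparse single cells.

    Each cell's contacts are a multinomial draw over its type's intensity
    (upper triangle), after an elementwise log-normal batch field shared
    by all cells of the same library.  A ``qc_fail_fraction`` of cells per
    filter is given deliberately failing QC values; everyone else passes.
    """
    rng = np.random.default_rng(pop.seed)
    n_types = pop.n_types
    cells: list[SyntheticCell] = []
    # one multiplicative batch field per library, shared across its cells
    base_spec = pop.type_specs[0]
    n = base_spec.n_bins
    iu, ju = np.triu_indices(n)
    batch_fields = {}
    for lib in pop.batch_labels:
        if pop.batch_effect > 0:
            batch_fields[lib] = np.exp(rng.normal(0.0, pop.batch_effect, size=iu.size))
        else:
            batch_fields[lib] = np.ones(iu.size)
    lams = []
    for spec in pop.type_specs:
        if spec.n_bins != n:
            raise ValueError("all cell types must share n_bins")
        lam = intensity_matrix(spec).matrix[iu, ju]
        lams.append(lam / lam.sum())
    lo, hi = pop.per_cell_depth
    idx = 0
    for t, spec in enumerate(pop.type_specs):
        for c in range(pop.cells_per_type):
            lib = pop.batch_labels[idx % len(pop.batch_labels)]
            p = lams[t] * batch_fields[lib]
            p = p / p.sum()
            fail_reads = rng.random() < pop.qc_fail_fraction
            fail_ratio = rng.random() < pop.qc_fail_fraction
            fail_frac = rng.random() < pop.qc_fail_fraction
            if fail_reads:
                depth = int(rng.integers(100, 1000))
            else:
                depth = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(depth, p)
            m = np.zeros((n, n))
            m[iu, ju] = counts
            m[ju, iu] = counts
            cmap = ContactMap(
                chrom=spec.chrom,
                bin_size=spec.bin_size,
                matrix=m,
                state="raw_counts",
            )
            ratio = float(rng.uniform(0.1, 0.9)) if fail_ratio else float(
                rng.uniform(1.2, 3.0)
            )
            frac = float(rng.uniform(0.5, 0.94)) if fail_frac else float(
                rng.uniform(0.96, 1.0)
            )
            cells.append(
                SyntheticCell(
                    cell_id=f"cell{idx:04d}",
                    cell_type=f"type{t}",
                    library=lib,
                    cmap=cmap,
                    unique_reads=depth,
                    intra_inter_ratio=ratio,
                    uniq_map_frac=frac,
                )
            )
            idx += 1
    return cells


def ground_truth(pop: CellPopulationSpec) -> tuple[list[str], pd.DataFrame]:
    """Return the type label per cell and the per-type TAD tables."""
    labels = [
        f"type{t}" for t in range(pop.n_types) for _ in range(pop.cells_per_type)
    ]
    rows = []
    for t, spec in enumerate(pop.type_specs):
        for s0, e0, b in spec.tads:
            rows.append(
                {"cell_type": f"type{t}", "start_bin": s0, "end_bin": e0, "boost": b}
            )
    tads = pd.DataFrame(rows, columns=["cell_type", "start_bin", "end_bin", "boost"])
    return labels, tads


def cells_metadata(cells: Sequence[SyntheticCell]) -> pd.DataFrame:
    """Tabulate cell metadata (TSV-ready: one row per cell)."""
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "type": c.cell_type,
                "library": c.library,
                "unique_reads": c.unique_reads,
                "intra_inter_ratio": c.intra_inter_ratio,
                "uniq_map_frac": c.uniq_map_frac,
            }
            for c in cells
        ]
    )
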