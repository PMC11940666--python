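"""Contact-map containers, file formats, balancing, scaling and tiling.

A :class:`ContactMap` holds one chromosome's symmetric contact matrix
together with its bin size and normalization state.  Maps move through
three states: ``raw_counts`` (integers straight from pairing),
``kr_balanced`` (after matrix balancing) and ``scaled01`` (clipped and
divided so entries lie in [0, 1], ready for the network).

Tiling into fixed-size square blocks (40 x 40 by default) and the exact
inverse merge are provided by :func:`split_blocks` / :func:`merge_blocks`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ContactMap",
    "BlockGrid",
    "read_coo",
    "write_coo",
    "read_npz",
    "write_npz",
    "kr_balance",
    "normalize01",
    "split_blocks",
    "merge_blocks",
]

_STATES = ("raw_counts", "kr_balanced", "scaled01")
_SYM_TOL = 1e-8


@dataclass
class ContactMap:
    """Symmetric nonnegative contact matrix for a single chromosome.

    Parameters
    ----------
    chrom:
        Chromosome label, e.g. ``"chr1"`` or ``"1"``.
    bin_size:
        Width of one genomic bin in base pairs.  Bins are 0-based,
        half-open intervals ``[i * bin_size, (i + 1) * bin_size)``.
    matrix:
        Dense ``(n_bins, n_bins)`` symmetric array of contact strengths.
    state:
        One of ``raw_counts``, ``kr_balanced``, ``scaled01``.
    scale:
        Divisor recorded by :func:`normalize01` (1.0 otherwise) so model
        output can be mapped back to the balanced-count scale.
    assembly:
        Free-text genome-assembly tag.
    """

    chrom: str
    bin_size: int
    matrix: np.ndarray
    state: str = "raw_counts"
    scale: float = 1.0
    assembly: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.validate()

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def validate(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {m.shape}")
        if not np.allclose(m, m.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("contact matrix must be symmetric (|M - M.T| <= 1e-8)")
        if m.size and m.min() < 0:
            raise ValueError("contact matrix entries must be nonnegative")
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {_STATES}")
        if self.state == "scaled01" and m.size and m.max() > 1.0 + 1e-12:
            raise ValueError("state=scaled01 requires max entry <= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def copy(self) -> "ContactMap":
        return replace(self, matrix=self.matrix.copy())


def read_coo(path, bin_size: int, n_bins: int, chrom: str = "chr?") -> ContactMap:
    """Read a sparse text contact list into a dense :class:`ContactMap`.

    Each line holds ``bin_i <TAB> bin_j <TAB> count`` with 0-based bin
    indices; ``#``-prefixed lines are comments.  Records are symmetrized
    (written to both ``(i, j)`` and ``(j, i)``) and duplicates summed.
    """
    m = np.zeros((n_bins, n_bins), dtype=np.float64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            i, j = int(parts[0]), int(parts[1])
            c = float(parts[2])
            if i < 0 or j < 0 or i >= n_bins or j >= n_bins:
                raise ValueError(
                    f"{path}:{lineno}: bin index ({i}, {j}) out of range for n_bins={n_bins}"
                )
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count {c}")
            m[i, j] += c
            if i != j:
                m[j, i] += c
    return ContactMap(chrom=chrom, bin_size=bin_size, matrix=m, state="raw_counts")


def write_coo(cmap: ContactMap, path) -> None:
    """Write the upper triangle of a map as ``bin_i\\tbin_j\\tcount`` lines.

    Only nonzero entries are written, sorted by ``(i, j)``; integers are
    written without a decimal point so the round trip is bit-stable.
    """
    m = cmap.matrix
    iu, ju = np.nonzero(np.triu(m))
    with open(path, "w") as fh:
        for i, j in zip(iu.tolist(), ju.tolist()):
            v = m[i, j]
            if float(v).is_integer():
                fh.write(f"{i}\t{j}\t{int(v)}\n")
            else:
                fh.write(f"{i}\t{j}\t{v!r}\n")


def write_npz(cmap: ContactMap, path) -> None:
    """Save a map as a compressed array archive (keys documented below)."""
    np.savez_compressed(
        path,
        matrix=cmap.matrix,
        bin_size=np.int64(cmap.bin_size),
        chrom=np.str_(cmap.chrom),
        state=np.str_(cmap.state),
        scale=np.float64(cmap.scale),
        assembly=np.str_(cmap.assembly),
    )


def read_npz(path) -> ContactMap:
    with np.load(path, allow_pickle=False) as z:
        return ContactMap(
            chrom=str(z["chrom"]),
            bin_size=int(z["bin_size"]),
            matrix=np.asarray(z["matrix"]),
            state=str(z["state"]),
            scale=float(z["scale"]),
            assembly=str(z["assembly"]),
        )


def kr_balance(
    cmap: ContactMap, tol: float = 1e-6, max_iter: int = 1000
) -> tuple[ContactMap, np.ndarray]:
    """Balance a raw contact matrix so all row sums are equal.

    Uses symmetric alternate scaling (Sinkhorn iteration): for symmetric
    nonnegative matrices this converges to the same doubly stochastic
    balanced matrix as Knight-Ruiz.  All-zero rows/columns are masked out
    and left untouched; their bias entries are reported as NaN.

    Returns the balanced map (state ``kr_balanced``) and the bias vector
    ``b`` such that ``balanced = diag(b) @ M @ diag(b)`` on unmasked bins.
    """
    if cmap.state != "raw_counts":
        raise ValueError(f"kr_balance expects raw_counts, got state={cmap.state!r}")
    m = cmap.matrix
    keep = m.sum(axis=1) > 0
    if not keep.any():
        raise ValueError(f"{cmap.chrom}: no nonzero row to balance")
    sub = m[np.ix_(keep, keep)]
    n = sub.shape[0]
    b = np.ones(n)
    converged = False
    for _ in range(max_iter):
        row = b * (sub @ b)  # row sums of diag(b) @ sub @ diag(b)
        if row.min() <= 0:
            raise ValueError(
                f"{cmap.chrom}: balancing broke down (zero row sum after masking)"
            )
        spread = (row.max() - row.min()) / row.mean()
        if spread < tol:
            converged = True
            break
        b = b / np.sqrt(row)
    if not converged:
        # final check after the last update
        row = b * (sub @ b)
        if (row.max() - row.min()) / row.mean() >= tol:
            raise RuntimeError(
                f"{cmap.chrom}: KR balancing did not converge in {max_iter} iterations"
            )
    balanced = np.array(m, dtype=np.float64)
    bsub = np.outer(b, b) * sub
    bsub = (bsub + bsub.T) / 2.0  # enforce exact symmetry against round-off
    balanced[np.ix_(keep, keep)] = bsub
    bias = np.full(m.shape[0], np.nan)
    bias[keep] = b
    out = replace(cmap, matrix=balanced, state="kr_balanced")
    return out, bias


def normalize01(cmap: ContactMap, clip_percentile: float = 99.9) -> ContactMap:
    """Clip at a percentile of the nonzero entries and scale into [0, 1].

    The divisor is recorded in ``scale`` so enhanced maps can be mapped
    back to the balanced-count scale.  An all-zero map is returned
    unchanged with ``scale = 1``.
    """
    m = cmap.matrix
    nz = m[m > 0]
    if nz.size == 0:
        return replace(cmap, matrix=m.copy(), state="scaled01", scale=1.0)
    cap = float(np.percentile(nz, clip_percentile))
    if cap <= 0:
        cap = float(nz.max())
    scaled = np.minimum(m, cap) / cap
    return replace(cmap, matrix=scaled, state="scaled01", scale=cap * cmap.scale)


@dataclass
class BlockGrid:
    """Ordered set of H x H tiles cut from a contact map.

    ``index`` records ``(chrom, row_origin, col_origin)`` in bin units for
    each tile so that :func:`merge_blocks` can reassemble the map exactly.
    """

    blocks: list[np.ndarray]
    index: list[tuple[str, int, int]]
    H: int
    source_n_bins: int
    bin_size: int = 0
    state: str = "scaled01"
    scale: float = 1.0
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if len(self.blocks) != len(self.index):
            raise ValueError("blocks and index must have equal length")
        for b in self.blocks:
            if b.shape != (self.H, self.H):
                raise ValueError(f"every block must be {self.H}x{self.H}, got {b.shape}")


def split_blocks(
    cmap: ContactMap,
    H: int = 40,
    stride: int | None = None,
    max_diag_bins: int | None = None,
) -> BlockGrid:
    """Cut a contact map into non-overlapping H x H tiles.

    Edge tiles are zero-padded on the right/bottom.  If ``max_diag_bins``
    is given, only tiles whose origins satisfy
    ``|row_origin - col_origin| <= max_diag_bins`` are kept, which
    restricts training to the informative near-diagonal band.
    """
    if H < 2:
        raise ValueError("H must be >= 2")
    stride = H if stride is None else stride
    n = cmap.n_bins
    if H > n:
        warnings.warn(
            f"block side H={H} exceeds n_bins={n}; emitting a single padded tile"
        )
    m = cmap.matrix
    blocks: list[np.ndarray] = []
    index: list[tuple[str, int, int]] = []
    origins = list(range(0, max(n, 1), stride))
    for r0 in origins:
        for c0 in origins:
            if max_diag_bins is not None and abs(r0 - c0) > max_diag_bins:
                continue
            tile = np.zeros((H, H), dtype=np.float64)
            rs, cs = min(H, n - r0), min(H, n - c0)
            if rs > 0 and cs > 0:
                tile[:rs, :cs] = m[r0 : r0 + rs, c0 : c0 + cs]
            blocks.append(tile)
            index.append((cmap.chrom, r0, c0))
    return BlockGrid(
        blocks=blocks,
        index=index,
        H=H,
        source_n_bins=n,
        bin_size=cmap.bin_size,
        state=cmap.state,
        scale=cmap.scale,
    )


def merge_blocks(grid: BlockGrid, symmetrize: bool = True) -> ContactMap:
    """Reassemble tiles into a contact map (inverse of :func:`split_blocks`).

    Padding is cropped; cells not covered by any tile (when the grid was
    diagonal-filtered) are zero.  Because the network does not enforce
    symmetry, the merged matrix is symmetrized as ``(M + M.T) / 2`` unless
    ``symmetrize=False``.
    """
    n = grid.source_n_bins
    H = grid.H
    m = np.zeros((n, n), dtype=np.float64)
    chroms = {idx[0] for idx in grid.index}
    if len(chroms) > 1:
        raise ValueError(f"grid mixes chromosomes: {sorted(chroms)}")
    for tile, (_, r0, c0) in zip(grid.blocks, grid.index):
        if r0 < 0 or c0 < 0 or r0 >= n or c0 >= n:
            raise ValueError(f"tile origin ({r0}, {c0}) outside source map of {n} bins")
        rs, cs = min(H, n - r0), min(H, n - c0)
        m[r0 : r0 + rs, c0 : c0 + cs] = tile[:rs, :cs]
    if symmetrize:
        m = (m + m.T) / 2.0
    m = np.clip(m, 0.0, None)
    chrom = next(iter(chroms)) if chroms else "chr?"
    return ContactMap(
        chrom=chrom,
        bin_size=grid.bin_size,
        matrix=m,
        state=grid.state,
        scale=grid.scale,
    )
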