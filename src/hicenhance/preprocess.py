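"""Training-pair construction: down-sampling, cell QC, pseudo-bulk, splits.

Bulk maps are binomially thinned to emulate shallow sequencing; single
cells pass quality filters, are ranked by genome-wide Pearson similarity,
and each cell's top-k same-type neighbours are stacked into a pseudo-bulk
map that serves as its high-depth training target.  Chromosomes are
partitioned into train/validation/test sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ContactMap

__all__ = [
    "CellRecord",
    "PseudoBulk",
    "downsample",
    "cell_qc",
    "cell_similarity",
    "build_pseudobulk",
    "chromosome_partition",
]


@dataclass
class CellRecord:
    """One cell's per-chromosome contact maps plus QC statistics."""

    cell_id: str
    maps: dict[str, ContactMap]
    cell_type: str | None = None
    library: str = ""
    unique_reads: int | None = None
    intra_inter_ratio: float | None = None
    uniq_map_frac: float | None = None

    def total_contacts(self) -> float:
        return float(sum(m.matrix.sum() for m in self.maps.values())) / 2.0


def from_synthetic(cells) -> list[CellRecord]:
    """Adapt :mod:`hicenhance.synthetic` cells to :class:`CellRecord`."""
    return [
        CellRecord(
            cell_id=c.cell_id,
            maps={c.cmap.chrom: c.cmap},
            cell_type=c.cell_type,
            library=c.library,
            unique_reads=c.unique_reads,
            intra_inter_ratio=c.intra_inter_ratio,
            uniq_map_frac=c.uniq_map_frac,
        )
        for c in cells
    ]


def downsample(cmap: ContactMap, ratio: float, seed: int = 0) -> ContactMap:
    """Binomially thin each contact count: ``c -> Binomial(c, ratio)``.

    Thinning a Poisson-sampled map at ratio ``r`` is distributionally
    identical to sequencing at ``r``-fold lower depth, which is why this
    is the standard way to simulate shallow libraries.  Requires integer
    raw counts (down-sample *before* normalization).
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    m = cmap.matrix
    if cmap.state != "raw_counts" or not np.allclose(m, np.round(m)):
        raise ValueError(
            "downsample requires integer raw counts; down-sample before normalization"
        )
    if ratio == 1.0:
        return cmap.copy()
    rng = np.random.default_rng(seed)
    n = cmap.n_bins
    iu, ju = np.triu_indices(n)
    thinned = rng.binomial(np.round(m[iu, ju]).astype(np.int64), ratio)
    out = np.zeros_like(m)
    out[iu, ju] = thinned
    out[ju, iu] = thinned
    return replace(cmap, matrix=out)


_QC_FIELDS = ("unique_reads", "intra_inter_ratio", "uniq_map_frac")


def cell_qc(
    cells: Sequence[CellRecord],
    min_unique: int = 1000,
    min_ratio: float = 1.0,
    min_uniq_frac: float = 0.95,
) -> tuple[list[CellRecord], list[tuple[str, list[str]]]]:
    """Filter cells on library-quality statistics.

    A cell is dropped iff ``unique_reads < min_unique`` OR
    ``intra_inter_ratio < min_ratio`` OR ``uniq_map_frac < min_uniq_frac``
    (strict inequalities).  Returns kept cells and, for each dropped
    cell, the list of reasons.
    """
    kept: list[CellRecord] = []
    dropped: list[tuple[str, list[str]]] = []
    for cell in cells:
        for f in _QC_FIELDS:
            if getattr(cell, f) is None:
                raise ValueError(f"cell {cell.cell_id}: missing QC field {f!r}")
        reasons = []
        if cell.unique_reads < min_unique:
            reasons.append("unique_reads")
        if cell.intra_inter_ratio < min_ratio:
            reasons.append("intra_inter_ratio")
        if cell.uniq_map_frac < min_uniq_frac:
            reasons.append("uniq_map_frac")
        if reasons:
            dropped.append((cell.cell_id, reasons))
        else:
            kept.append(cell)
    return kept, dropped


def _upper_vector(cell: CellRecord) -> np.ndarray:
    parts = []
    for chrom in sorted(cell.maps):
        m = cell.maps[chrom].matrix
        iu, ju = np.triu_indices(m.shape[0])
        parts.append(m[iu, ju])
    return np.concatenate(parts)


def cell_similarity(a: CellRecord, b: CellRecord) -> float:
    """Genome-wide Pearson correlation between two cells.

    Computed over the concatenated upper-triangle vectors of all shared
    chromosomes; a zero-variance vector yields 0 with a warning.
    """
    shared = sorted(set(a.maps) & set(b.maps))
    if not shared:
        raise ValueError(f"cells {a.cell_id} and {b.cell_id} share no chromosome")
    va = np.concatenate(
        [a.maps[c].matrix[np.triu_indices(a.maps[c].n_bins)] for c in shared]
    )
    vb = np.concatenate(
        [b.maps[c].matrix[np.triu_indices(b.maps[c].n_bins)] for c in shared]
    )
    if va.shape != vb.shape:
        raise ValueError("cells do not share a bin grid")
    if va.std() == 0 or vb.std() == 0:
        warnings.warn("zero-variance contact vector; similarity defined as 0")
        return 0.0
    return float(np.corrcoef(va, vb)[0, 1])


@dataclass
class PseudoBulk:
    """Sum of an anchor cell and its k most-similar same-type neighbours."""

    anchor_cell_id: str
    member_ids: list[str]
    k: int
    maps: dict[str, ContactMap]

    def __post_init__(self) -> None:
        if len(self.member_ids) != self.k + 1:
            raise ValueError("member_ids must hold the anchor plus k neighbours")


def build_pseudobulk(
    anchor: CellRecord, candidates: Sequence[CellRecord], k: int = 10
) -> PseudoBulk:
    """Stack the anchor with its top-k most-correlated candidates.

    Candidates are restricted to the anchor's cell type when labels are
    available (a global pool triggers a warning); ties in similarity are
    broken by lexicographic ``cell_id``.  Maps are elementwise sums per
    chromosome, so the pseudo-bulk total is the sum of member totals.
    """
    pool = [c for c in candidates if c.cell_id != anchor.cell_id]
    if anchor.cell_type is not None:
        typed = [c for c in pool if c.cell_type == anchor.cell_type]
        if len(typed) < len(pool) or not typed:
            pool = typed if typed else pool
        if not typed:
            warnings.warn(
                f"no candidates share cell type {anchor.cell_type!r}; using global pool"
            )
    else:
        warnings.warn("anchor cell type unknown; selecting global top-k")
    if k > len(pool):
        warnings.warn(f"only {len(pool)} candidates available; using all of them")
        k = len(pool)
    scored = sorted(
        pool, key=lambda c: (-cell_similarity(anchor, c), c.cell_id)
    )
    members = [anchor] + scored[:k]
    maps: dict[str, ContactMap] = {}
    for chrom in sorted(anchor.maps):
        acc = np.zeros_like(anchor.maps[chrom].matrix)
        for cell in members:
            acc += cell.maps[chrom].matrix
        maps[chrom] = replace(anchor.maps[chrom], matrix=acc)
    return PseudoBulk(
        anchor_cell_id=anchor.cell_id,
        member_ids=[c.cell_id for c in members],
        k=k,
        maps=maps,
    )


_DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 23))
_DEFAULT_TEST = frozenset({"4", "14", "16", "20"})
_DEFAULT_VAL = frozenset({"2", "6", "10", "12"})


def chromosome_partition(
    autosomes: Sequence[str] = _DEFAULT_AUTOSOMES,
    test: Sequence[str] | None = None,
    val: Sequence[str] | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Split autosomes into disjoint train/validation/test sets.

    Defaults follow the human 22-autosome layout: chromosomes 4, 14, 16
    and 20 held out for testing, 2, 6, 10 and 12 for validation, and the
    remaining 14 for training.
    """
    autosomes = [str(a) for a in autosomes]
    test_set = set(str(c) for c in (test if test is not None else _DEFAULT_TEST))
    val_set = set(str(c) for c in (val if val is not None else _DEFAULT_VAL))
    if test_set & val_set:
        raise ValueError(f"test and validation sets overlap: {sorted(test_set & val_set)}")
    missing = (test_set | val_set) - set(autosomes)
    if missing:
        raise ValueError(f"chromosomes not in autosome list: {sorted(missing)}")
    train = [a for a in autosomes if a not in test_set and a not in val_set]
    val_l = [a for a in autosomes if a in val_set]
    test_l = [a for a in autosomes if a in test_set]
    return train, val_l, test_l
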