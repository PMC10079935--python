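"""Data model and readers/writers for expression matrices, gene sets and CFU tables.

The three central containers are :class:`ExpressionMatrix` (genes x samples
signal values with a per-sample condition label and a linear/log10 scale
flag), :class:`GeneSetCollection` (named gene sets such as GO terms or
regulons), and :class:`CfuTimecourse` (viable-cell counts over time for one
strain/replicate).  On disk they are exchanged as plain text: TSV for the
expression matrix, MSigDB-dialect GMT for gene sets, and a four-column CSV
(``strain,replicate,time_h,cfu_per_ml``) for colony counts.

Gene identifiers are matched by exact, case-sensitive string equality
throughout; annotation is assumed to be supplied pre-matched to the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ltsp_sig")

LINEAR = "linear"
LOG10 = "log10"
_SCALES = (LINEAR, LOG10)


class DataError(ValueError):
    """Malformed input data (duplicate IDs, non-numeric cells, bad scale...)."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples signal matrix with condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.  Entries are
        linear signal in pM-like units, or log10-transformed values,
        according to ``scale``.
    condition_of
        Mapping sample ID -> condition label (e.g. ``"LL"``, ``"STS"``,
        ``"LTSsn"``).  Every sample in ``values`` must be present.
    scale
        Either ``"linear"`` or ``"log10"``.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise DataError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise DataError(f"duplicate gene IDs: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise DataError(f"duplicate sample IDs: {dups}")
        missing = [s for s in cols if s not in self.condition_of]
        if missing:
            raise DataError(f"samples missing from condition map: {missing}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise DataError("expression values must be numeric")

    # -- convenience accessors ------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance along samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition_of[s] == condition]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        """New matrix sharing this one's condition map."""
        cond = {s: self.condition_of[s] for s in values.columns}
        return ExpressionMatrix(values=values, condition_of=cond,
                                scale=self.scale if scale is None else scale)


def read_expression_matrix(
    path: str | Path,
    condition_map: str | Path | Mapping[str, str],
) -> ExpressionMatrix:
    """Read a TSV signal matrix (first column gene ID, header = sample IDs).

    ``condition_map`` is either an inline mapping sample -> condition or a
    path to a two-column TSV (``sample_id<TAB>condition``, no header
    required; a header line ``sample_id\tcondition`` is tolerated).
    The matrix is returned on the linear scale with file order preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise DataError(f"{path}: duplicate gene IDs {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise DataError(f"{path}: duplicate sample IDs {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        g = bad.index[bad.any(axis=1)][0]
        s = bad.columns[bad.loc[g]][0]
        raise DataError(f"{path}: non-numeric value at gene {g!r}, sample {s!r}: "
                        f"{df.loc[g, s]!r}")
    if numeric.isna().to_numpy().any():
        raise DataError(f"{path}: missing values in matrix body")
    cond = dict(_load_condition_map(condition_map))
    return ExpressionMatrix(values=numeric.astype(float), condition_of=cond, scale=LINEAR)


def _load_condition_map(condition_map: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(condition_map, Mapping):
        return dict(condition_map)
    out: dict[str, str] = {}
    for line_no, line in enumerate(Path(condition_map).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise DataError(f"{condition_map}:{line_no}: expected 2 tab-separated "
                            f"fields, got {len(parts)}")
        if parts == ["sample_id", "condition"]:
            continue
        if parts[0] in out:
            raise DataError(f"{condition_map}:{line_no}: duplicate sample {parts[0]!r}")
        out[parts[0]] = parts[1]
    return out


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            condition_path: str | Path | None = None) -> None:
    """Write the matrix as TSV (12 significant digits) and optionally the
    condition map as a two-column TSV."""
    df = matrix.values
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")
    if condition_path is not None:
        with open(condition_path, "w") as fh:
            fh.write("sample_id\tcondition\n")
            for s in matrix.sample_ids:
                fh.write(f"{s}\t{matrix.condition_of[s]}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise DataError(f"gene set {self.set_id!r} has duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms / regulons) with member gene IDs."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if sid != gs.set_id:
                raise DataError(f"key {sid!r} does not match set_id {gs.set_id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def add(self, gs: GeneSet) -> None:
        if gs.set_id in self.sets:
            raise DataError(f"duplicate set_id {gs.set_id!r}")
        self.sets[gs.set_id] = gs

    def set_ids(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate member genes within a line are deduplicated (first occurrence
    kept) with a logged warning; a duplicate set_id or a line with fewer
    than 3 fields is a hard error.
    """
    coll = GeneSetCollection(provenance=str(path))
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"{path}:{line_no}: GMT line has {len(parts)} fields, "
                            "need at least 3 (id, description, >=1 gene)")
        set_id, name, *genes = parts
        genes = [g for g in genes if g != ""]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            logger.warning("%s:%d: set %s: %d duplicate member gene(s) removed",
                           path, line_no, set_id, len(genes) - len(deduped))
        if set_id in coll:
            raise DataError(f"{path}:{line_no}: duplicate set_id {set_id!r}")
        coll.add(GeneSet(set_id=set_id, name=name, members=tuple(deduped)))
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.name, *gs.members]) + "\n")


def filter_sets_by_size(
    collection: GeneSetCollection,
    universe: Sequence[str],
    min_size: int = 6,
    max_size: int = 200,
) -> GeneSetCollection:
    """Keep sets whose membership, intersected with ``universe``, has size in
    [min_size, max_size]; member lists are replaced by that intersection.

    Set size is counted after intersecting with the analyzed universe, since
    all downstream enrichment statistics are defined only over analyzed genes.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    if len(universe) == 0:
        raise DataError("empty universe")
    uni = set(universe)
    out = GeneSetCollection(provenance=collection.provenance)
    for gs in collection:
        members = tuple(g for g in gs.members if g in uni)
        if min_size <= len(members) <= max_size:
            out.add(GeneSet(set_id=gs.set_id, name=gs.name, members=members))
    logger.info("size filter [%d, %d]: %d of %d sets kept",
                min_size, max_size, len(out), len(collection))
    return out


# ---------------------------------------------------------------------------
# CFU time courses
# ---------------------------------------------------------------------------

@dataclass
class CfuTimecourse:
    """Viable-cell counts (CFU-derived, cells/mL) over time for one
    strain/replicate.  Times are in hours, strictly increasing, first = 0."""

    strain: str
    replicate: int
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.counts.ndim != 1:
            raise DataError("times and counts must be 1-D")
        if len(self.times) != len(self.counts):
            raise DataError("times and counts must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise DataError(f"{self.strain}/{self.replicate}: times must be "
                            "strictly increasing")
        if np.any(self.counts < 0):
            raise DataError(f"{self.strain}/{self.replicate}: negative counts")

    @property
    def n_timepoints(self) -> int:
        return len(self.times)


def read_cfu_table(path: str | Path) -> list[CfuTimecourse]:
    """Read CFU time courses from CSV with header
    ``strain,replicate,time_h,cfu_per_ml``."""
    df = pd.read_csv(path)
    required = ["strain", "replicate", "time_h", "cfu_per_ml"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    out = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=False):
        grp = grp.sort_values("time_h")
        out.append(CfuTimecourse(strain=str(strain), replicate=int(rep),
                                 times=grp["time_h"].to_numpy(),
                                 counts=grp["cfu_per_ml"].to_numpy()))
    return out


def write_cfu_table(timecourses: Iterable[CfuTimecourse], path: str | Path) -> None:
    rows = []
    for tc in timecourses:
        for t, n in zip(tc.times, tc.counts):
            rows.append((tc.strain, tc.replicate, t, n))
    pd.DataFrame(rows, columns=["strain", "replicate", "time_h", "cfu_per_ml"]) \
        .to_csv(path, index=False, float_format="%.12g")
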