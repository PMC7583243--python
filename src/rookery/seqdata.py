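"""Sequence input, validation and haplotype bookkeeping.

The universal input of the pipeline is a multi-FASTA alignment of mtDNA
control-region sequences together with a tab-delimited population map that
assigns every sequence to a nesting unit at up to three nested geographic
levels (rookery -> island -> beach).  Sequences are kept as plain strings over
``{A, C, G, T, N, -}``; ``N`` and ``-`` are treated as missing data and are
excluded pairwise-complete in all distance computations (literature
compilations of control-region fragments differ in length, so missing sites
are unavoidable).

The haplotype table — distinct sequences crossed with per-unit counts — is the
substrate of haplotype diversity, frequency-mode F_ST and the exact test of
differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "HaplotypeTable",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "attach_population_map",
    "trim_to_window",
    "collapse_haplotypes",
    "STUDY_FRAGMENT_LENGTH",
    "STUDY_CONSENSUS_LENGTH",
    "STUDY_TRIM_WINDOW",
    "encode_sequences",
    "decode_matrix",
]

#: Length of the "long fragment" of the loggerhead control region as amplified.
STUDY_FRAGMENT_LENGTH = 780
#: Consensus length every sequence is trimmed to before analysis.
STUDY_CONSENSUS_LENGTH = 674
#: Default 0-based half-open trim window producing the 674-bp consensus from a
#: 780-bp fragment.  The exact offset within the fragment is not fixed by the
#: nomenclature, so this is a configurable convention (centred), not a claim.
STUDY_TRIM_WINDOW = (53, 53 + STUDY_CONSENSUS_LENGTH)

VALID_CHARS = frozenset("ACGTN-")
MISSING_CHARS = frozenset("N-")

# Base encoding: purines 0/1, pyrimidines 2/3 so that the K2P transition
# partner of x is x ^ 1 and the transversion partners are x ^ 2 and x ^ 3.
# Missing (N or -) encodes to 255.
BASE_TO_CODE = {"A": 0, "G": 1, "C": 2, "T": 3, "N": 255, "-": 255}
CODE_TO_BASE = np.array(list("AGCT"), dtype="U1")
MISSING_CODE = 255

_ENCODE_LUT = np.full(256, 254, dtype=np.uint8)
for _b, _c in BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c

LEVEL_COLUMNS = ("level1", "level2", "level3")


class AlignmentError(ValueError):
    """Raised for malformed sequence input or inconsistent population maps."""


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode aligned sequences as a (n, length) uint8 matrix (missing=255)."""
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = _ENCODE_LUT[raw].reshape(len(seqs), -1)
    return mat


def decode_matrix(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences` (missing decodes to ``N``)."""
    letters = np.where(mat == MISSING_CODE, "N", CODE_TO_BASE[np.minimum(mat, 3)])
    return ["".join(row) for row in letters]


@dataclass
class Alignment:
    """An aligned set of sequences plus an optional nested population map.

    Parameters
    ----------
    ids
        Unique sequence identifiers.
    seqs
        Equal-length strings over ``{A, C, G, T, N, -}`` (upper case).
    labels
        Optional DataFrame indexed by sequence id with columns
        ``level1``/``level2``/``level3`` (deeper levels may be missing).
    unit_coords
        ``{unit name: (longitude, latitude)}`` in decimal degrees.
    unit_order
        Per level, the order in which units first appeared in the population
        map.  All downstream unit orderings are taken from here so that
        permutation tests are reproducible.
    """

    ids: list[str]
    seqs: list[str]
    labels: pd.DataFrame | None = None
    unit_coords: dict[str, tuple[float, float]] = field(default_factory=dict)
    unit_order: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if not self.ids:
            raise AlignmentError("empty alignment")
        seen: set[str] = set()
        dups = [i for i in self.ids if i in seen or seen.add(i)]
        if dups:
            raise AlignmentError(f"duplicate sequence ids: {sorted(set(dups))}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            bad = [i for i, s in zip(self.ids, self.seqs)
                   if len(s) != len(self.seqs[0])]
            raise AlignmentError(
                f"sequences are not all the same length (offending ids: {bad})")
        if lengths == {0}:
            raise AlignmentError("zero-length sequences")
        self.seqs = [s.upper() for s in self.seqs]
        bad_ids = [i for i, s in zip(self.ids, self.seqs)
                   if not set(s) <= VALID_CHARS]
        if bad_ids:
            raise AlignmentError(
                f"invalid characters (allowed: A,C,G,T,N,-) in: {bad_ids}")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        """(n, length) uint8 encoding (see :func:`encode_sequences`)."""
        return encode_sequences(self.seqs)

    # -- population structure -------------------------------------------
    def has_level(self, level: int) -> bool:
        if self.labels is None:
            return False
        col = LEVEL_COLUMNS[level - 1]
        return col in self.labels.columns and self.labels[col].notna().all()

    def labels_at(self, level: int) -> pd.Series:
        """Per-sequence unit label at *level*, aligned with ``ids``."""
        if not self.has_level(level):
            raise AlignmentError(f"no complete labels at level {level}")
        return self.labels.loc[self.ids, LEVEL_COLUMNS[level - 1]]

    def units(self, level: int) -> list[str]:
        """Unit names at *level* in population-map order."""
        if level in self.unit_order:
            return list(self.unit_order[level])
        lab = self.labels_at(level)
        return list(dict.fromkeys(lab))

    def unit_indices(self, level: int) -> dict[str, np.ndarray]:
        lab = self.labels_at(level).to_numpy()
        return {u: np.flatnonzero(lab == u) for u in self.units(level)}

    def unit_sizes(self, level: int) -> dict[str, int]:
        return {u: len(ix) for u, ix in self.unit_indices(level).items()}

    def subset(self, indices: Iterable[int]) -> "Alignment":
        idx = list(indices)
        ids = [self.ids[i] for i in idx]
        seqs = [self.seqs[i] for i in idx]
        labels = self.labels.loc[ids].copy() if self.labels is not None else None
        return Alignment(ids, seqs, labels, dict(self.unit_coords),
                         {k: list(v) for k, v in self.unit_order.items()})


@dataclass
class HaplotypeTable:
    """Distinct haplotypes crossed with per-unit counts.

    ``counts`` has shape (n_haplotypes, n_units); column sums are the unit
    sample sizes.  Rows are ordered by decreasing total count, ties broken
    lexicographically by sequence, so output is deterministic.
    """

    haplotypes: list[str]
    counts: np.ndarray
    unit_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.haplotypes), len(self.unit_names)):
            raise AlignmentError("haplotype count matrix has wrong shape")
        if (self.counts < 0).any():
            raise AlignmentError("negative haplotype counts")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise AlignmentError("duplicate haplotype strings")

    @property
    def n_per_unit(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def unit_counts(self, unit: str) -> np.ndarray:
        return self.counts[:, self.unit_names.index(unit)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"H{i+1}" for i in range(self.n_haplotypes)],
                            columns=self.unit_names)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned multi-FASTA file (wrapped or single-line).

    Mixed case is normalised to upper case.  Raises :class:`AlignmentError`
    for empty files, duplicate ids, non-IUPAC-subset characters or unequal
    sequence lengths, naming the offending records.
    """
    path = Path(path)
    if not path.exists():
        raise AlignmentError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return Alignment(ids, seqs)


def write_fasta(a: Alignment, path: str | Path, width: int = 70) -> None:
    """Write the alignment back to FASTA (fixed line width)."""
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(a.ids, a.seqs)]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for k in range(0, len(s), width):
                fh.write(s[k:k + width] + "\n")


def attach_population_map(a: Alignment, map_path: str | Path) -> Alignment:
    """Attach a tab-delimited population map to an alignment.

    The map has a header ``id level1 level2 level3 lon lat``; ``level2``,
    ``level3``, ``lon`` and ``lat`` may be empty.  Coordinates are registered
    under the deepest non-empty unit label of each row.  Map ids absent from
    the alignment produce a warning; alignment sequences without a map entry
    are an error.  Duplicate map rows are accepted (with a warning) when
    consistent, rejected otherwise.
    """
    df = pd.read_csv(map_path, sep="\t", dtype=str)
    if "id" not in df.columns or "level1" not in df.columns:
        raise AlignmentError("population map needs at least 'id' and 'level1'")
    for col in LEVEL_COLUMNS + ("lon", "lat"):
        if col not in df.columns:
            df[col] = pd.NA

    if df["id"].duplicated().any():
        dup_ids = df.loc[df["id"].duplicated(), "id"].tolist()
        full = df.drop_duplicates()
        if full["id"].duplicated().any():
            bad = full.loc[full["id"].duplicated(), "id"].tolist()
            raise AlignmentError(f"conflicting duplicate map rows for: {bad}")
        warnings.warn(f"duplicate (consistent) map rows for ids: {sorted(set(dup_ids))}",
                      stacklevel=2)
        df = full

    known = set(a.ids)
    extra = [i for i in df["id"] if i not in known]
    if extra:
        warnings.warn(f"map ids absent from alignment (ignored): {extra}",
                      stacklevel=2)
        df = df[df["id"].isin(known)]
    missing = [i for i in a.ids if i not in set(df["id"])]
    if missing:
        raise AlignmentError(f"sequences without a population-map entry: {missing}")

    unit_order: dict[int, list[str]] = {}
    for lvl, col in enumerate(LEVEL_COLUMNS, start=1):
        vals = [v for v in df[col] if pd.notna(v) and v != ""]
        unit_order[lvl] = list(dict.fromkeys(vals))

    unit_coords = dict(a.unit_coords)
    for _, row in df.iterrows():
        if pd.isna(row["lon"]) or pd.isna(row["lat"]):
            continue
        deepest = None
        for col in LEVEL_COLUMNS:
            if pd.notna(row[col]) and row[col] != "":
                deepest = row[col]
        if deepest is not None:
            unit_coords[deepest] = (float(row["lon"]), float(row["lat"]))

    labels = (df.set_index("id")[list(LEVEL_COLUMNS)]
              .replace("", pd.NA).loc[a.ids])
    return Alignment(list(a.ids), list(a.seqs), labels, unit_coords, unit_order)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def trim_to_window(a: Alignment, start: int, end: int) -> Alignment:
    """Trim all sequences to the 0-based half-open window [start, end)."""
    if not (0 <= start < end <= a.length):
        raise AlignmentError(
            f"trim window [{start}, {end}) outside alignment of length {a.length}")
    seqs = [s[start:end] for s in a.seqs]
    labels = a.labels.copy() if a.labels is not None else None
    return Alignment(list(a.ids), seqs, labels, dict(a.unit_coords),
                     {k: list(v) for k, v in a.unit_order.items()})


def _haplotype_key(seq: str) -> bool:
    return any(c in MISSING_CHARS for c in seq)


def collapse_haplotypes(a: Alignment, level: int) -> HaplotypeTable:
    """Collapse identical sequences into a haplotype x unit count table.

    Haplotype identity is exact string equality over the non-missing sites of
    both sequences.  A sequence containing missing sites whose observed sites
    match an existing complete haplotype is merged into it; if it matches
    several, it joins the most frequent one (ties broken by lexicographically
    smaller haplotype) — a deterministic, frequency-parsimonious rule.
    """
    units = a.units(level)
    lab = a.labels_at(level).to_numpy()
    unit_col = {u: j for j, u in enumerate(units)}

    complete_counts: dict[str, np.ndarray] = {}
    incomplete: list[tuple[str, str]] = []
    for s, u in zip(a.seqs, lab):
        if _haplotype_key(s):
            incomplete.append((s, u))
        else:
            complete_counts.setdefault(s, np.zeros(len(units), dtype=np.int64))
            complete_counts[s][unit_col[u]] += 1

    incomplete_counts: dict[str, np.ndarray] = {}
    for s, u in incomplete:
        obs = [(i, c) for i, c in enumerate(s) if c not in MISSING_CHARS]
        matches = [h for h in complete_counts
                   if all(h[i] == c for i, c in obs)]
        if matches:
            best = max(matches, key=lambda h: (complete_counts[h].sum(),
                                               [-ord(c) for c in h]))
            complete_counts[best][unit_col[u]] += 1
        else:
            incomplete_counts.setdefault(s, np.zeros(len(units), dtype=np.int64))
            incomplete_counts[s][unit_col[u]] += 1

    merged = {**complete_counts, **incomplete_counts}
    order = sorted(merged, key=lambda h: (-merged[h].sum(), h))
    counts = np.stack([merged[h] for h in order]) if order else \
        np.zeros((0, len(units)), dtype=np.int64)
    return HaplotypeTable(order, counts, units)


def write_population_map(a: Alignment, path: str | Path) -> None:
    """Write the population map back out in the dialect read by
    :func:`attach_population_map`."""
    if a.labels is None:
        raise AlignmentError("alignment has no population labels")
    rows = []
    for i in a.ids:
        row = {"id": i}
        deepest = None
        for col in LEVEL_COLUMNS:
            v = a.labels.loc[i, col] if col in a.labels.columns else pd.NA
            row[col] = "" if pd.isna(v) else v
            if row[col]:
                deepest = row[col]
        lon, lat = a.unit_coords.get(deepest, (None, None))
        row["lon"] = "" if lon is None else lon
        row["lat"] = "" if lat is None else lat
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
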