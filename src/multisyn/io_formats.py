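"""Native genome/link/feature text formats and converters from aligner outputs.

Native formats are whitespace-delimited text. Coordinates are 1-based, fully
closed intervals. ``#`` starts a comment line; blank lines are skipped. Any
reader transparently accepts gzip-compressed input (sniffed by magic bytes,
not extension).

Genome / feature files: ``seq_id  start  end  [key=value ...]``
Link files: ``seqA startA endA seqB startB endB [key=value ...]``; an
inverted block is encoded by ``end < start`` on exactly one side.
"""

from __future__ import annotations

import enum
import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import FormatError

logger = logging.getLogger("multisyn")

__all__ = [
    "AttrMap",
    "ChromRecord",
    "GenomeDef",
    "Orientation",
    "LinkRecord",
    "FeatureRecord",
    "parse_attr_fields",
    "read_genome_file",
    "read_link_file",
    "read_feature_file",
    "write_genome_file",
    "write_link_file",
    "write_feature_file",
    "convert_paf",
    "convert_mummer_coords",
    "convert_mcscanx",
    "convert_syri",
    "SYRI_COLOR_TABLE",
]


class AttrMap:
    """Ordered key=value attribute set with case-insensitive keys.

    Keys are stored lower-cased; values are kept verbatim and never empty.
    Duplicate keys (after case-folding) resolve last-wins with a warning.
    Round-trips losslessly through ``key=value`` token serialization.
    """

    __slots__ = ("_entries",)

    def __init__(self, entries: Iterable[tuple[str, str]] = ()):
        self._entries: dict[str, str] = {}
        for key, value in entries:
            self.set(key, value)

    def set(self, key: str, value: str) -> None:
        key = key.lower()
        if not key:
            raise ValueError("attribute key must be non-empty")
        if not value:
            raise ValueError(f"attribute {key!r} has an empty value")
        self._entries[key] = str(value)

    def get(self, key: str, default: str | None = None) -> str | None:
        return self._entries.get(key.lower(), default)

    def __contains__(self, key: str) -> bool:
        return key.lower() in self._entries

    def __getitem__(self, key: str) -> str:
        return self._entries[key.lower()]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._entries.items()

    def __eq__(self, other: object) -> bool:
        if isinstance(other, AttrMap):
            return self._entries == other._entries
        if isinstance(other, dict):
            return self._entries == {k.lower(): v for k, v in other.items()}
        return NotImplemented

    def __repr__(self) -> str:
        return f"AttrMap({dict(self._entries)!r})"

    def copy(self) -> "AttrMap":
        return AttrMap(self._entries.items())

    def to_tokens(self) -> list[str]:
        return [f"{k}={v}" for k, v in self._entries.items()]


def parse_attr_fields(
    tokens: Sequence[str], *, path: str | None = None, line: int | None = None
) -> AttrMap:
    """Parse optional ``key=value`` tokens into an :class:`AttrMap`.

    Order of first occurrence is preserved; a duplicate key (case-folded)
    overwrites the stored value and logs a warning. A token without ``=``
    raises :class:`FormatError` naming the file/line/token.
    """
    attrs = AttrMap()
    for token in tokens:
        if "=" not in token:
            raise FormatError(
                f"malformed attribute token {token!r} (expected key=value)",
                path=path,
                line=line,
            )
        key, _, value = token.partition("=")
        if not key or not value:
            raise FormatError(
                f"malformed attribute token {token!r} (empty key or value)",
                path=path,
                line=line,
            )
        if key.lower() in attrs:
            logger.warning(
                "%s%sduplicate attribute key %r: last occurrence wins",
                f"{path}: " if path else "",
                f"line {line}: " if line else "",
                key.lower(),
            )
        attrs.set(key, value)
    return attrs


@dataclass(frozen=True)
class ChromRecord:
    """One chromosome/sequence: id plus a closed 1-based interval."""

    seq_id: str
    start: int
    end: int
    attrs: AttrMap = field(default_factory=AttrMap)

    def __post_init__(self) -> None:
        if not self.seq_id or any(ch.isspace() for ch in self.seq_id):
            raise ValueError(f"invalid seq_id {self.seq_id!r}")
        if self.start < 1:
            raise ValueError(f"{self.seq_id}: start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"{self.seq_id}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeDef:
    """An ordered set of chromosomes for one genome."""

    name: str
    chroms: list[ChromRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.chroms:
            if c.seq_id in seen:
                raise ValueError(f"duplicate seq_id {c.seq_id!r} in genome {self.name!r}")
            seen.add(c.seq_id)

    def chrom(self, seq_id: str) -> ChromRecord:
        for c in self.chroms:
            if c.seq_id == seq_id:
                return c
        raise KeyError(seq_id)

    def __contains__(self, seq_id: str) -> bool:
        return any(c.seq_id == seq_id for c in self.chroms)


class Orientation(enum.Enum):
    SAME = "same"
    INVERTED = "inverted"


@dataclass(frozen=True)
class LinkRecord:
    """A pair of genomic intervals joining two genomes.

    Stored normalized (start <= end on both sides); the inversion sign lives
    in :attr:`orientation`.
    """

    seq_a: str
    start_a: int
    end_a: int
    seq_b: str
    start_b: int
    end_b: int
    orientation: Orientation = Orientation.SAME
    attrs: AttrMap = field(default_factory=AttrMap)

    def __post_init__(self) -> None:
        for seq, s, e in ((self.seq_a, self.start_a, self.end_a),
                          (self.seq_b, self.start_b, self.end_b)):
            if not seq:
                raise ValueError("link sequence id must be non-empty")
            if s < 1 or e < s:
                raise ValueError(f"invalid link interval {seq}:{s}-{e}")

    @classmethod
    def from_raw(
        cls,
        seq_a: str, start_a: int, end_a: int,
        seq_b: str, start_b: int, end_b: int,
        attrs: AttrMap | None = None,
        *, path: str | None = None, line: int | None = None,
    ) -> "LinkRecord":
        """Build from file-order coordinates, deriving the orientation.

        Orientation is inverted iff exactly one of the two intervals is
        written descending; both descending is equivalent to neither.
        """
        inv_a = end_a < start_a
        inv_b = end_b < start_b
        if inv_a:
            start_a, end_a = end_a, start_a
        if inv_b:
            start_b, end_b = end_b, start_b
        orientation = Orientation.INVERTED if inv_a != inv_b else Orientation.SAME
        try:
            return cls(seq_a, start_a, end_a, seq_b, start_b, end_b,
                       orientation, attrs or AttrMap())
        except ValueError as exc:
            raise FormatError(str(exc), path=path, line=line) from exc

    @property
    def inverted(self) -> bool:
        return self.orientation is Orientation.INVERTED

    def key(self) -> tuple:
        """Coordinate+orientation identity, ignoring attributes."""
        return (self.seq_a, self.start_a, self.end_a,
                self.seq_b, self.start_b, self.end_b, self.orientation)


@dataclass(frozen=True)
class FeatureRecord:
    """A highlighted region on one sequence (CDS/UTR/TE/SNP/...)."""

    seq_id: str
    start: int
    end: int
    attrs: AttrMap = field(default_factory=AttrMap)

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("feature seq_id must be non-empty")
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"invalid feature interval {self.seq_id}:{self.start}-{self.end}")

    @property
    def feature_type(self) -> str | None:
        return self.attrs.get("feature")


# ---------------------------------------------------------------------------
# line-level plumbing

def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzip-compressed text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, whitespace-split tokens) for data lines."""
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped.split()


def _int(token: str, what: str, path: str | Path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(
            f"non-integer {what} {token!r}", path=str(path), line=lineno
        ) from None


# ---------------------------------------------------------------------------
# native readers

def read_genome_file(path: str | Path, name: str | None = None) -> GenomeDef:
    """Read a sequence-length file into a :class:`GenomeDef`.

    Each data line needs >= 3 columns (seq_id, start, end); columns 4+ are
    attribute tokens. File order is preserved; duplicate seq_ids are errors.
    """
    path = Path(path)
    chroms: list[ChromRecord] = []
    seen: set[str] = set()
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise FormatError(
                f"expected >=3 columns, got {len(cols)}", path=str(path), line=lineno)
        seq_id = cols[0]
        start = _int(cols[1], "start", path, lineno)
        end = _int(cols[2], "end", path, lineno)
        attrs = parse_attr_fields(cols[3:], path=str(path), line=lineno)
        if seq_id in seen:
            raise FormatError(f"duplicate seq_id {seq_id!r}", path=str(path), line=lineno)
        seen.add(seq_id)
        try:
            chroms.append(ChromRecord(seq_id, start, end, attrs))
        except ValueError as exc:
            raise FormatError(str(exc), path=str(path), line=lineno) from exc
    return GenomeDef(name=name or path.stem, chroms=chroms)


def read_link_file(path: str | Path) -> list[LinkRecord]:
    """Read a link file (>=6 columns per data line) into normalized records."""
    path = Path(path)
    links: list[LinkRecord] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 6:
            raise FormatError(
                f"expected >=6 columns, got {len(cols)}", path=str(path), line=lineno)
        seq_a, seq_b = cols[0], cols[3]
        sa = _int(cols[1], "startA", path, lineno)
        ea = _int(cols[2], "endA", path, lineno)
        sb = _int(cols[4], "startB", path, lineno)
        eb = _int(cols[5], "endB", path, lineno)
        attrs = parse_attr_fields(cols[6:], path=str(path), line=lineno)
        links.append(LinkRecord.from_raw(seq_a, sa, ea, seq_b, sb, eb, attrs,
                                         path=str(path), line=lineno))
    return links


def read_feature_file(path: str | Path) -> list[FeatureRecord]:
    """Read a highlight/feature region file; seq_ids may repeat."""
    path = Path(path)
    feats: list[FeatureRecord] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 3:
            raise FormatError(
                f"expected >=3 columns, got {len(cols)}", path=str(path), line=lineno)
        start = _int(cols[1], "start", path, lineno)
        end = _int(cols[2], "end", path, lineno)
        attrs = parse_attr_fields(cols[3:], path=str(path), line=lineno)
        try:
            feats.append(FeatureRecord(cols[0], start, end, attrs))
        except ValueError as exc:
            raise FormatError(str(exc), path=str(path), line=lineno) from exc
    return feats


# ---------------------------------------------------------------------------
# native writers

def write_genome_file(genome: GenomeDef, path: str | Path) -> None:
    if not genome.chroms:
        raise ValueError(f"genome {genome.name!r} has no chromosomes to write")
    with open(path, "w", encoding="utf-8") as fh:
        for c in genome.chroms:
            cols = [c.seq_id, str(c.start), str(c.end)] + c.attrs.to_tokens()
            fh.write("\t".join(cols) + "\n")


def write_link_file(links: Sequence[LinkRecord], path: str | Path) -> None:
    """Write links; inverted records are serialized with end_b < start_b."""
    with open(path, "w", encoding="utf-8") as fh:
        for lk in links:
            sb, eb = lk.start_b, lk.end_b
            if lk.inverted:
                sb, eb = eb, sb
            cols = [lk.seq_a, str(lk.start_a), str(lk.end_a),
                    lk.seq_b, str(sb), str(eb)] + lk.attrs.to_tokens()
            fh.write("\t".join(cols) + "\n")


def write_feature_file(feats: Sequence[FeatureRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in feats:
            cols = [f.seq_id, str(f.start), str(f.end)] + f.attrs.to_tokens()
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# converters

def convert_paf(
    path: str | Path, min_block_len: int = 0
) -> tuple[tuple[GenomeDef, GenomeDef], list[LinkRecord]]:
    """Convert minimap2 PAF alignments to native links.

    Returns ``((query_genome, target_genome), links)``. PAF coordinates are
    0-based half-open and become 1-based closed (start+1, end unchanged).
    Strand ``-`` yields an inverted link. Lines whose alignment-block length
    (column 11) is below *min_block_len* are filtered; malformed lines are
    skipped with a warning.
    """
    path = Path(path)
    links: list[LinkRecord] = []
    q_lens: dict[str, int] = {}
    t_lens: dict[str, int] = {}
    skipped = 0
    for lineno, cols in _data_lines(path):
        if len(cols) < 12:
            skipped += 1
            logger.warning("%s:%d: malformed PAF line (<12 columns), skipped",
                           path, lineno)
            continue
        try:
            qname, qlen = cols[0], int(cols[1])
            qstart, qend = int(cols[2]), int(cols[3])
            strand = cols[4]
            tname, tlen = cols[5], int(cols[6])
            tstart, tend = int(cols[7]), int(cols[8])
            block_len = int(cols[10])
        except ValueError:
            skipped += 1
            logger.warning("%s:%d: malformed PAF line, skipped", path, lineno)
            continue
        if strand not in "+-" or qend <= qstart or tend <= tstart:
            skipped += 1
            logger.warning("%s:%d: malformed PAF line, skipped", path, lineno)
            continue
        q_lens.setdefault(qname, qlen)
        t_lens.setdefault(tname, tlen)
        if block_len < min_block_len:
            continue
        orientation = Orientation.INVERTED if strand == "-" else Orientation.SAME
        links.append(LinkRecord(qname, qstart + 1, qend, tname, tstart + 1, tend,
                                orientation))
    if skipped:
        logger.warning("%s: skipped %d malformed PAF line(s)", path, skipped)
    query = GenomeDef("query", [ChromRecord(n, 1, ln) for n, ln in q_lens.items()])
    target = GenomeDef("target", [ChromRecord(n, 1, ln) for n, ln in t_lens.items()])
    return (query, target), links


def convert_mummer_coords(path: str | Path) -> list[LinkRecord]:
    """Convert MUMmer ``show-coords`` tabular output to native links.

    Accepts output with or without the banner/header block. A data row must
    start with four integer columns (ref start/end, query start/end) and end
    with the reference and query sequence IDs; a query interval written
    descending marks an inversion.
    """
    path = Path(path)
    links: list[LinkRecord] = []
    saw_any_line = False
    for lineno, cols in _data_lines(path):
        saw_any_line = True
        if len(cols) < 6:
            continue  # banner / prompt lines
        try:
            s1, e1, s2, e2 = (int(cols[0]), int(cols[1]), int(cols[2]), int(cols[3]))
        except ValueError:
            continue  # header row like [S1] [E1] ...
        ref_id, qry_id = cols[-2], cols[-1]
        try:
            links.append(LinkRecord.from_raw(ref_id, s1, e1, qry_id, s2, e2,
                                             path=str(path), line=lineno))
        except FormatError:
            raise
    if saw_any_line and not links:
        raise FormatError(
            "no alignment rows found; expected show-coords tabular output "
            "(ref_start ref_end qry_start qry_end ... ref_id qry_id)",
            path=str(path))
    return links


def convert_mcscanx(
    collinearity_path: str | Path, gene_pos_path: str | Path
) -> list[LinkRecord]:
    """Convert an MCScanX collinearity file to block-span links.

    *gene_pos_path* is a tab/space-delimited table ``gene_id seq start end``.
    Each alignment block becomes one link spanning min(start)..max(end) of
    its genes on each side; blocks flagged ``minus`` are inverted.
    """
    gene_pos: dict[str, tuple[str, int, int]] = {}
    gp = Path(gene_pos_path)
    for lineno, cols in _data_lines(gp):
        if len(cols) < 4:
            raise FormatError("expected gene_id seq start end", path=str(gp), line=lineno)
        gene_pos[cols[0]] = (cols[1],
                             _int(cols[2], "start", gp, lineno),
                             _int(cols[3], "end", gp, lineno))

    path = Path(collinearity_path)
    blocks: list[tuple[bool, list[tuple[str, str]]]] = []
    current: list[tuple[str, str]] | None = None
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            stripped = line.strip()
            if stripped.startswith("## Alignment"):
                minus = stripped.split()[-1].lower() == "minus"
                current = []
                blocks.append((minus, current))
            elif stripped.startswith("#") or not stripped:
                continue
            elif current is not None:
                # "  0-  0:\tgeneA\tgeneB\t  0" — gene ids are the two
                # tokens after the pair index prefix
                body = stripped.split(":", 1)[-1].split()
                if len(body) >= 2:
                    current.append((body[0], body[1]))

    missing = sorted({g for _, pairs in blocks for pair in pairs for g in pair
                      if g not in gene_pos})
    if missing:
        raise FormatError(
            "gene IDs absent from position table: " + ", ".join(missing),
            path=str(path))

    links: list[LinkRecord] = []
    for minus, pairs in blocks:
        if not pairs:
            continue
        a_pos = [gene_pos[a] for a, _ in pairs]
        b_pos = [gene_pos[b] for _, b in pairs]
        seq_a = a_pos[0][0]
        seq_b = b_pos[0][0]
        links.append(LinkRecord(
            seq_a, min(p[1] for p in a_pos), max(p[2] for p in a_pos),
            seq_b, min(p[1] for p in b_pos), max(p[2] for p in b_pos),
            Orientation.INVERTED if minus else Orientation.SAME))
    return links


#: default fill per structural-annotation class (overridable downstream)
SYRI_COLOR_TABLE: dict[str, str] = {
    "SYN": "#b0b0b0",
    "SYNAL": "#d0d0d0",
    "INV": "#e69f00",
    "INVAL": "#f0c040",
    "TRANS": "#56b4e9",
    "TRANSAL": "#9ad3f2",
    "DUP": "#009e73",
    "DUPAL": "#66c2a5",
}
_SYRI_DEFAULT_COLOR = "#808080"


def convert_syri(path: str | Path) -> list[LinkRecord]:
    """Convert SyRI tabular output to native links.

    Keeps interval-bearing record classes (rows whose reference and query
    coordinates are all integers); the annotation type is recorded as a
    ``svtype`` attribute, INV-class records are marked inverted, and a fill
    color from :data:`SYRI_COLOR_TABLE` is attached (unknown types keep a
    default color with a warning).
    """
    path = Path(path)
    links: list[LinkRecord] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < 11:
            continue
        ref_chr, ref_s, ref_e = cols[0], cols[1], cols[2]
        qry_chr, qry_s, qry_e = cols[5], cols[6], cols[7]
        svtype = cols[10]
        try:
            rs, re_ = int(ref_s), int(ref_e)
            qs, qe = int(qry_s), int(qry_e)
        except ValueError:
            continue  # NOTAL/SNP-style rows without both intervals
        if rs < 1 or qs < 1:
            continue
        inverted = svtype.upper().startswith("INV")
        fill = SYRI_COLOR_TABLE.get(svtype.upper())
        if fill is None:
            fill = _SYRI_DEFAULT_COLOR
            logger.warning("%s:%d: unknown SyRI annotation type %r, default color",
                           path, lineno, svtype)
        attrs = AttrMap([("svtype", svtype), ("fill", fill)])
        rec = LinkRecord.from_raw(ref_chr, rs, re_, qry_chr, qs, qe, attrs,
                                  path=str(path), line=lineno)
        if inverted and not rec.inverted:
            rec = LinkRecord(rec.seq_a, rec.start_a, rec.end_a,
                             rec.seq_b, rec.start_b, rec.end_b,
                             Orientation.INVERTED, rec.attrs)
        links.append(rec)
    return links
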