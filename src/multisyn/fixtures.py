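"""Deterministic toy multi-genome datasets for tests and demos.

One integer seed fully determines the output bytes. Each file type draws
from its own named PRNG stream (``Random(f"{seed}:{stream}")``) so adding a
new file type never perturbs the existing ones.

Besides the native genome/link/feature files and a ready-to-run config, the
generator writes PAF / show-coords / SyRI / MCScanX dialect files encoding
*exactly the same links*, which is the converters' principal test oracle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .errors import MultisynError
from .io_formats import (AttrMap, ChromRecord, FeatureRecord, GenomeDef,
                         LinkRecord, Orientation, write_feature_file,
                         write_genome_file, write_link_file)

__all__ = ["FixtureSpec", "make_fixture", "TRIANGLE_PLACEMENTS"]

_FEATURE_TYPES = ("CDS", "UTR", "TE", "SNP")

#: (move_to_x, move_to_y, rotate_chr, zoom_chr) per genome for the
#: three-genome triangular layout template (sides of an equilateral
#: triangle, traversed clockwise in the y-down canvas frame)
TRIANGLE_PLACEMENTS = (
    (600.0, 100.0, 60.0, 0.6),
    (900.0, 620.0, 180.0, 0.6),
    (300.0, 620.0, 300.0, 0.6),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_genomes: int = 3
    chroms_per_genome: int = 2
    chrom_len_range: tuple[int, int] = (200_000, 1_000_000)
    n_links: int = 8
    inversion_fraction: float = 0.25
    n_features: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_genomes <= 20):
            raise MultisynError(
                f"n_genomes must be in 2..20, got {self.n_genomes}")
        if self.chroms_per_genome < 1 or self.n_links < 0 or self.n_features < 0:
            raise MultisynError("counts must be non-negative (>=1 chromosome)")
        if not (0.0 <= self.inversion_fraction <= 1.0):
            raise MultisynError("inversion_fraction must be in [0, 1]")
        lo, hi = self.chrom_len_range
        if lo < 1000 or hi < lo:
            raise MultisynError("chrom_len_range must satisfy 1000 <= lo <= hi")


def _stream(spec: FixtureSpec, name: str) -> random.Random:
    return random.Random(f"{spec.seed}:{name}")


def _make_genomes(spec: FixtureSpec) -> list[GenomeDef]:
    rng = _stream(spec, "genomes")
    genomes = []
    for g in range(1, spec.n_genomes + 1):
        chroms = [
            ChromRecord(f"g{g}c{k}", 1,
                        rng.randint(*spec.chrom_len_range))
            for k in range(1, spec.chroms_per_genome + 1)
        ]
        genomes.append(GenomeDef(f"genome{g}", chroms))
    return genomes


def _make_links(spec: FixtureSpec,
                genomes: list[GenomeDef]) -> list[list[LinkRecord]]:
    """One link set per adjacent genome pair, coordinates within bounds."""
    rng = _stream(spec, "links")
    all_sets: list[list[LinkRecord]] = []
    for i in range(spec.n_genomes - 1):
        ga, gb = genomes[i], genomes[i + 1]
        records: list[LinkRecord] = []
        for _ in range(spec.n_links):
            ca = rng.choice(ga.chroms)
            cb = rng.choice(gb.chroms)
            span_a = rng.randint(ca.length // 20, max(ca.length // 5,
                                                      ca.length // 20 + 1))
            span_b = rng.randint(cb.length // 20, max(cb.length // 5,
                                                      cb.length // 20 + 1))
            sa = rng.randint(1, ca.length - span_a)
            sb = rng.randint(1, cb.length - span_b)
            inverted = rng.random() < spec.inversion_fraction
            records.append(LinkRecord(
                ca.seq_id, sa, sa + span_a, cb.seq_id, sb, sb + span_b,
                Orientation.INVERTED if inverted else Orientation.SAME))
        all_sets.append(records)
    return all_sets


def _make_features(spec: FixtureSpec, genome: GenomeDef) -> list[FeatureRecord]:
    rng = _stream(spec, "features")
    feats: list[FeatureRecord] = []
    for n in range(spec.n_features):
        chrom = rng.choice(genome.chroms)
        span = rng.randint(max(chrom.length // 200, 1),
                           max(chrom.length // 50, 2))
        start = rng.randint(1, max(chrom.length - span, 1))
        ftype = _FEATURE_TYPES[n % len(_FEATURE_TYPES)]
        feats.append(FeatureRecord(chrom.seq_id, start, start + span,
                                   AttrMap([("feature", ftype)])))
    return feats


# ---------------------------------------------------------------------------
# converter-dialect encodings of the same links

def _write_paf(links: list[LinkRecord], ga: GenomeDef, gb: GenomeDef,
               path: Path) -> None:
    lens_a = {c.seq_id: c.length for c in ga.chroms}
    lens_b = {c.seq_id: c.length for c in gb.chroms}
    with open(path, "w", encoding="utf-8") as fh:
        for lk in links:
            la = lk.end_a - lk.start_a + 1
            lb = lk.end_b - lk.start_b + 1
            fh.write("\t".join(map(str, [
                lk.seq_a, lens_a[lk.seq_a], lk.start_a - 1, lk.end_a,
                "-" if lk.inverted else "+",
                lk.seq_b, lens_b[lk.seq_b], lk.start_b - 1, lk.end_b,
                min(la, lb), max(la, lb), 60,
            ])) + "\n")


def _write_coords(links: list[LinkRecord], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("/tmp/ref.fa /tmp/qry.fa\nNUCMER\n\n")
        fh.write("[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[TAGS]\n")
        for lk in links:
            s2, e2 = lk.start_b, lk.end_b
            if lk.inverted:
                s2, e2 = e2, s2
            fh.write("\t".join(map(str, [
                lk.start_a, lk.end_a, s2, e2,
                lk.end_a - lk.start_a + 1, lk.end_b - lk.start_b + 1,
                "97.50", lk.seq_a, lk.seq_b,
            ])) + "\n")


def _write_syri(links: list[LinkRecord], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n, lk in enumerate(links, start=1):
            svtype = "INV" if lk.inverted else "SYN"
            fh.write("\t".join(map(str, [
                lk.seq_a, lk.start_a, lk.end_a, "-", "-",
                lk.seq_b, lk.start_b, lk.end_b,
                f"{svtype}{n}", "-", svtype, "-",
            ])) + "\n")


def _write_mcscanx(links: list[LinkRecord], coll_path: Path,
                   gene_pos_path: Path) -> None:
    gene_rows: list[tuple[str, str, int, int]] = []
    with open(coll_path, "w", encoding="utf-8") as fh:
        fh.write("############### Statistics ###############\n")
        fh.write("# Number of collinear blocks: %d\n" % len(links))
        for n, lk in enumerate(links):
            sign = "minus" if lk.inverted else "plus"
            a1, a2 = f"gA{n}s", f"gA{n}e"
            b1, b2 = f"gB{n}s", f"gB{n}e"
            gene_rows += [(a1, lk.seq_a, lk.start_a, lk.start_a),
                          (a2, lk.seq_a, lk.end_a, lk.end_a),
                          (b1, lk.seq_b, lk.start_b, lk.start_b),
                          (b2, lk.seq_b, lk.end_b, lk.end_b)]
            fh.write(f"## Alignment {n}: score=100.0 e_value=0 N=2 "
                     f"{lk.seq_a}&{lk.seq_b} {sign}\n")
            fh.write(f"{n:3d}-  0:\t{a1}\t{b1}\t  0\n")
            fh.write(f"{n:3d}-  1:\t{a2}\t{b2}\t  0\n")
    with open(gene_pos_path, "w", encoding="utf-8") as fh:
        for gene, seq, s, e in gene_rows:
            fh.write(f"{gene}\t{seq}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------

def _config_text(spec: FixtureSpec, genomes: list[GenomeDef]) -> str:
    lines: list[str] = ["# generated fixture configuration"]
    for g in range(1, spec.n_genomes + 1):
        lines.append(f"Genome = genome{g}.len")
        if g == 1 and spec.n_features:
            lines.append("Feature = features_genome1.txt")
    for i in range(1, spec.n_genomes):
        lines.append(f"Link = links_{i}_{i + 1}.link {i} {i + 1}")
    lines += ["", "SetParaFor = global", "ChrHeight = 14", "ChrSpacing = 12"]
    lines += ["", "SetParaFor = GenomeALL", "ShowCoordinates = true"]
    if spec.n_genomes == 3:
        # triangular layout: three rotated tracks forming a closed triangle
        for g, (mx, my, rot, zoom) in enumerate(TRIANGLE_PLACEMENTS, start=1):
            lines += ["", f"SetParaFor = Genome{g}",
                      f"MoveToX = {mx}", f"MoveToY = {my}",
                      f"RotateChr = {rot}", f"ZoomChr = {zoom}"]
        for i in range(1, spec.n_genomes):
            lines += ["", f"SetParaFor = Link{i}", "Style = 2",
                      "StyleUpDown = DownDown"]
    return "\n".join(lines) + "\n"


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture tree; returns a name → path map.

    Files: ``genome<i>.len``, ``links_<i>_<j>.link``,
    ``features_genome1.txt``, ``config.conf``, plus per-pair converter
    dialect files ``pair_<i>_<j>.{paf,coords,syri,collinearity}`` and
    ``pair_<i>_<j>.gene_pos``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise MultisynError(f"cannot create output directory {out}: {exc}")

    paths: dict[str, Path] = {}
    genomes = _make_genomes(spec)
    link_sets = _make_links(spec, genomes)

    for g, genome in enumerate(genomes, start=1):
        p = out / f"genome{g}.len"
        write_genome_file(genome, p)
        paths[f"genome{g}"] = p

    for i, links in enumerate(link_sets, start=1):
        j = i + 1
        p = out / f"links_{i}_{j}.link"
        write_link_file(links, p)
        paths[f"links_{i}_{j}"] = p
        ga, gb = genomes[i - 1], genomes[j - 1]
        pair = f"pair_{i}_{j}"
        _write_paf(links, ga, gb, out / f"{pair}.paf")
        _write_coords(links, out / f"{pair}.coords")
        _write_syri(links, out / f"{pair}.syri")
        _write_mcscanx(links, out / f"{pair}.collinearity",
                       out / f"{pair}.gene_pos")
        for ext in ("paf", "coords", "syri", "collinearity", "gene_pos"):
            paths[f"{pair}.{ext}"] = out / f"{pair}.{ext}"

    if spec.n_features:
        p = out / "features_genome1.txt"
        write_feature_file(_make_features(spec, genomes[0]), p)
        paths["features"] = p

    conf = out / "config.conf"
    conf.write_text(_config_text(spec, genomes), encoding="utf-8")
    paths["config"] = conf
    return paths
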