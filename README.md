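# multisyn

Configuration-driven visualization of syntenic relationships across multiple
(N) genomes. multisyn reads simple whitespace-delimited genome/link/feature
files, resolves a cascading parameter configuration, lays genome tracks out
on a canvas with per-genome move/rotate/zoom transforms, and renders the
scene as deterministic SVG (optionally PNG). Converters turn minimap2 PAF,
MUMmer `show-coords`, MCScanX collinearity and SyRI output into the native
link format.

## Input formats

Coordinates are 1-based, fully closed. Fields are separated by any run of
tabs/spaces; `#` starts a comment line. Optional trailing fields are
unordered `key=value` attributes (keys case-insensitive, e.g. `fill=green`).

* **Genome (sequence length) file** — one line per chromosome:
  `seq_id start end [attrs...]`. Order defines the track layout.
* **Link file** — `seqA startA endA seqB startB endB [attrs...]`. Writing
  one interval descending (`end < start`) marks the block as inverted.
* **Feature file** — same 3+ column shape as genome files;
  `feature=CDS|UTR|TE|SNP` selects a default color, `fill=` overrides.

All readers accept plain or gzip-compressed files.

## Configuration

```ini
# file declarations (ordered; paths relative to the config file)
Genome = rice_a.len            # Genome1
Genome = rice_b.len            # Genome2
Feature = rice_b.features      # attaches to the most recent Genome
Link = ab.link 1 2             # Link1 joins Genome1 and Genome2

SetParaFor = global            # applies everywhere
ChrHeight = 18

SetParaFor = GenomeALL         # all genomes, overrides global
ShowCoordinates = true

SetParaFor = Genome2           # one genome, overrides GenomeALL
MoveToX = 120
MoveToY = 300
RotateChr = 60
ZoomChr = 0.8
ZoomRegion = Chr6:12914310:18879240

SetParaFor = Link1             # one link set, overrides global
Style = 4                      # 1 straight, 2-5 Bezier profiles
StyleUpDown = DownDown         # ribbon ends at up/down edges of A and B
HeightRatio = 1.2              # scales the Bezier control-point offsets
```

Precedence is defaults < `global` < `GenomeALL` < `GenomeN` (and defaults <
`global` < `LinkN`); a record's own attributes in a link file override the
resolved link parameters for that record only. Genome keys: `MoveToX`,
`MoveToY`, `RotateChr`, `ZoomChr`, `ZoomRegion`, `Label`, `LabelColor`,
`LabelPosition`, `ShowLabel`, `ShowCoordinates`, `ChrHeight`, `ChrSpacing`,
`SpeRegionWidthRatio`, `Fill`, `Stroke`, `RoundedEnds`. Link keys: `Style`,
`StyleUpDown`, `HeightRatio`, `Fill`, `Stroke`, `Opacity`. Keys are
case- and underscore-insensitive; colors accept SVG names and `#RRGGBB(AA)`;
booleans accept `1/0/true/false/yes/no`.

## CLI

```sh
# render (the minimal call: a configuration and an output prefix)
multisyn plot -c config.conf -o figure            # writes figure.svg
multisyn plot -c config.conf -o figure --png --dpi 192
multisyn plot -c config.conf -o figure --dump-scene --dump-config --report json

# convert aligner output to native link files
multisyn convert paf aln.paf --min-len 1000 -o out     # + out.a.len/out.b.len
multisyn convert mummer aln.coords -o out
multisyn convert mcscanx blocks.collinearity genes.tsv -o out
multisyn convert syri syri.out -o out                  # links carry svtype=

# deterministic toy datasets (native + all converter dialects + config)
multisyn fixtures --genomes 3 --seed 1 -o demo/
multisyn plot -c demo/config.conf -o demo/fig
```

`multisyn convert mcscanx` needs a gene position table (`gene_id seq start
end` per line). Exit code is 0 iff no errors; warnings never change it.

## Layout model

Each genome is placed on a local baseline (origin at the left end of its
first chromosome, y growing downward) and mapped to the canvas by
`translate(MoveToX, MoveToY) ∘ rotate(RotateChr) ∘ scale(ZoomChr)` about
that origin. Genomes without `MoveToY` stack top-to-bottom in declaration
order. `ZoomRegion=seq:start:end` restricts a genome to one chromosome
slice; links are clipped to the rendered windows with the partner interval
rescaled proportionally. Ribbon styles 2-5 are cubic Bezier bands whose
control points are offset vertically from the anchors by
`f(style) · HeightRatio · slot pitch` with `f` = (0.5, 0.5), (0.25, 0.25),
(0.75, 0.75, pointing outward from the chromosome edge — the wrap-around
look), (0.8, 0.2).
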