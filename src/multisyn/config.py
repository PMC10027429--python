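"""Configuration file parsing and parameter-cascade resolution.

The configuration is an INI-like flat text file. Three kinds of lines:

* declarations, ordered at top level::

      Genome  = rice_a.len            # declares Genome1, Genome2, ... in order
      Feature = rice_a.features       # attaches to the most recent Genome
      Link    = ab.link 1 2           # link file between Genome1 and Genome2

* a scope header opening a parameter block::

      SetParaFor = global | GenomeALL | Genome<N> | Link<N>

* ``key = value`` parameter lines belonging to the open block.

``#`` starts a comment; blank lines are ignored. Parameter keys are
case-insensitive and underscore-insensitive (``MoveToX`` == ``move_to_x``).

Resolution cascade (later overrides earlier, key by key):

* genomes: built-in defaults < global < GenomeALL < GenomeN
* links:   built-in defaults < global < LinkN

Within one scope, later blocks override earlier ones. Per-record attributes
from a link file override the resolved LinkParams for that record only
(see :func:`effective_link_params`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .errors import ConfigError
from .io_formats import AttrMap

logger = logging.getLogger("multisyn")

__all__ = [
    "ScopeKind",
    "ScopeId",
    "RegionSpec",
    "ConfigModel",
    "GenomeParams",
    "LinkParams",
    "parse_config",
    "parse_region",
    "resolve_genome_params",
    "resolve_link_params",
    "effective_link_params",
    "dump_resolved_config",
]


# ---------------------------------------------------------------------------
# scopes

class ScopeKind:
    GLOBAL = "global"
    GENOME_ALL = "genome_all"
    GENOME_N = "genome_n"
    LINK_N = "link_n"


@dataclass(frozen=True)
class ScopeId:
    kind: str
    index: int | None = None

    def __post_init__(self) -> None:
        if self.kind in (ScopeKind.GLOBAL, ScopeKind.GENOME_ALL):
            if self.index is not None:
                raise ValueError(f"scope {self.kind} takes no index")
        else:
            if self.index is None or self.index < 1:
                raise ValueError(f"scope {self.kind} needs an index >= 1")


_SCOPE_RE = re.compile(r"^(global|genomeall|genome(\d+)|link(\d+))$", re.IGNORECASE)


def _parse_scope(text: str) -> ScopeId:
    m = _SCOPE_RE.match(text.strip())
    if not m:
        raise ConfigError(
            f"invalid SetParaFor scope {text!r} "
            "(expected global, GenomeALL, Genome<N> or Link<N>)")
    if m.group(2) is not None:
        return ScopeId(ScopeKind.GENOME_N, int(m.group(2)))
    if m.group(3) is not None:
        return ScopeId(ScopeKind.LINK_N, int(m.group(3)))
    if m.group(1).lower() == "global":
        return ScopeId(ScopeKind.GLOBAL)
    return ScopeId(ScopeKind.GENOME_ALL)


# ---------------------------------------------------------------------------
# value parsing helpers

@dataclass(frozen=True)
class RegionSpec:
    """A ``seq:start:end`` window of interest."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("region seq_id must be non-empty")
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")


def parse_region(text: str) -> RegionSpec:
    """Parse a ``seq:start:end`` specifier, e.g. ``Chr6:12914310:18879240``."""
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise ConfigError(
            f"invalid region {text!r}: expected seq:start:end with 3 fields")
    seq, s, e = parts
    try:
        start, end = int(s), int(e)
    except ValueError:
        raise ConfigError(f"invalid region {text!r}: non-integer coordinates") from None
    try:
        return RegionSpec(seq, start, end)
    except ValueError as exc:
        raise ConfigError(f"invalid region {text!r}: {exc}") from None


_TRUE = {"1", "true", "yes", "on"}
_FALSE = {"0", "false", "no", "off"}

_NAMED_COLOR_RE = re.compile(r"^[a-zA-Z]+$")
_HEX_COLOR_RE = re.compile(r"^#[0-9a-fA-F]{6}([0-9a-fA-F]{2})?$")


def _parse_bool(value: str, key: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ConfigError(f"{key}: expected a boolean (1/0/true/false/yes/no), got {value!r}")


def _parse_float(value: str, key: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ConfigError(f"{key}: expected a number, got {value!r}") from None


def _parse_int(value: str, key: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ConfigError(f"{key}: expected an integer, got {value!r}") from None


def _parse_color(value: str, key: str) -> str:
    v = value.strip()
    if v.lower() == "none" or _NAMED_COLOR_RE.match(v) or _HEX_COLOR_RE.match(v):
        return v
    raise ConfigError(f"{key}: expected an SVG named color or #RRGGBB(AA), got {value!r}")


# ---------------------------------------------------------------------------
# parameter objects

_LABEL_POSITIONS = ("left", "right", "top", "bottom")
_STYLE_UP_DOWN = ("UpUp", "UpDown", "DownUp", "DownDown")


@dataclass(frozen=True)
class GenomeParams:
    """Effective drawing parameters for one genome track."""

    move_to_x: float = 0.0
    move_to_y: float | None = None  # None -> stacked slot default
    rotate_chr: float = 0.0
    zoom_chr: float = 1.0
    zoom_region: RegionSpec | None = None
    label_text: str | None = None  # None -> genome name
    label_color: str = "black"
    label_position: str = "left"
    show_label: bool = True
    show_coordinates: bool = False
    chr_height: float = 20.0
    chr_spacing: float = 10.0
    spe_region_width_ratio: float = 1.0
    fill: str = "#b8c8dc"
    stroke: str = "black"
    rounded_ends: bool = True
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.zoom_chr <= 0:
            raise ConfigError(f"zoom_chr must be > 0, got {self.zoom_chr}")
        if self.spe_region_width_ratio <= 0:
            raise ConfigError(
                f"spe_region_width_ratio must be > 0, got {self.spe_region_width_ratio}")
        if self.chr_height <= 0 or self.chr_spacing < 0:
            raise ConfigError("chr_height must be > 0 and chr_spacing >= 0")
        if self.label_position not in _LABEL_POSITIONS:
            raise ConfigError(
                f"label_position must be one of {_LABEL_POSITIONS}, "
                f"got {self.label_position!r}")


@dataclass(frozen=True)
class LinkParams:
    """Effective drawing parameters for one link set."""

    style: int = 2
    style_up_down: str = "UpDown"
    height_ratio: float = 1.0
    fill: str = "#c9d8ea"
    stroke: str = "none"
    opacity: float = 0.72
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.style not in (1, 2, 3, 4, 5):
            raise ConfigError(f"link style must be in 1..5, got {self.style}")
        if self.style_up_down not in _STYLE_UP_DOWN:
            raise ConfigError(
                f"style_up_down must be one of {_STYLE_UP_DOWN}, "
                f"got {self.style_up_down!r}")
        if self.height_ratio <= 0:
            raise ConfigError(f"height_ratio must be > 0, got {self.height_ratio}")
        if not (0.0 <= self.opacity <= 1.0):
            raise ConfigError(f"opacity must be in [0, 1], got {self.opacity}")


def _canon_style_up_down(value: str, key: str) -> str:
    v = value.strip().lower()
    for option in _STYLE_UP_DOWN:
        if option.lower() == v:
            return option
    raise ConfigError(
        f"{key}: expected one of {_STYLE_UP_DOWN}, got {value!r}")


def _norm_key(key: str) -> str:
    return key.lower().replace("_", "").replace("-", "")


# normalized config key -> (dataclass field, converter)
_GENOME_KEYS: dict[str, tuple[str, object]] = {
    "movetox": ("move_to_x", _parse_float),
    "movetoy": ("move_to_y", _parse_float),
    "rotatechr": ("rotate_chr", _parse_float),
    "zoomchr": ("zoom_chr", _parse_float),
    "zoomregion": ("zoom_region", lambda v, k: parse_region(v)),
    "label": ("label_text", lambda v, k: v),
    "labeltext": ("label_text", lambda v, k: v),
    "labelcolor": ("label_color", _parse_color),
    "labelposition": ("label_position", lambda v, k: v.strip().lower()),
    "showlabel": ("show_label", _parse_bool),
    "showcoordinates": ("show_coordinates", _parse_bool),
    "chrheight": ("chr_height", _parse_float),
    "chrspacing": ("chr_spacing", _parse_float),
    "speregionwidthratio": ("spe_region_width_ratio", _parse_float),
    "fill": ("fill", _parse_color),
    "stroke": ("stroke", _parse_color),
    "roundedends": ("rounded_ends", _parse_bool),
}

_LINK_KEYS: dict[str, tuple[str, object]] = {
    "style": ("style", _parse_int),
    "styleupdown": ("style_up_down", _canon_style_up_down),
    "heightratio": ("height_ratio", _parse_float),
    "fill": ("fill", _parse_color),
    "stroke": ("stroke", _parse_color),
    "opacity": ("opacity", _parse_float),
}


# ---------------------------------------------------------------------------
# model

@dataclass
class ConfigModel:
    """Parsed configuration: ordered entries plus scoped parameter blocks."""

    genome_entries: list[tuple[str, list[str]]] = field(default_factory=list)
    link_entries: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    blocks: list[tuple[ScopeId, AttrMap]] = field(default_factory=list)
    base_dir: Path = field(default_factory=Path)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_entries)

    @property
    def n_links(self) -> int:
        return len(self.link_entries)

    def validate(self) -> None:
        for scope, _ in self.blocks:
            if scope.kind == ScopeKind.GENOME_N and scope.index > self.n_genomes:
                raise ConfigError(
                    f"SetParaFor=Genome{scope.index} but only "
                    f"{self.n_genomes} genome(s) declared")
            if scope.kind == ScopeKind.LINK_N and scope.index > self.n_links:
                raise ConfigError(
                    f"SetParaFor=Link{scope.index} but only "
                    f"{self.n_links} link file(s) declared")
        for path, (ga, gb) in self.link_entries:
            for g in (ga, gb):
                if not (1 <= g <= self.n_genomes):
                    raise ConfigError(
                        f"link file {path!r} references genome {g}, "
                        f"but only {self.n_genomes} declared")
            if ga == gb:
                raise ConfigError(
                    f"link file {path!r} must reference two distinct genomes")

    def resolve_path(self, p: str) -> Path:
        pp = Path(p)
        return pp if pp.is_absolute() else self.base_dir / pp


def parse_config(path: str | Path) -> ConfigModel:
    """Parse a configuration file into a :class:`ConfigModel`.

    Entries and blocks keep file order. Unknown parameter keys inside a
    block are retained (with a warning) for forward compatibility; dangling
    Genome/Link indices are errors.
    """
    path = Path(path)
    model = ConfigModel(base_dir=path.parent)
    current: AttrMap | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value, got {line!r}")
            key, _, value = line.partition("=")
            key_n = _norm_key(key.strip())
            value = value.strip()
            if not value:
                raise ConfigError(f"{path}:{lineno}: empty value for {key.strip()!r}")

            if key_n == "genome":
                model.genome_entries.append((value, []))
                current = None
            elif key_n == "feature":
                if not model.genome_entries:
                    raise ConfigError(
                        f"{path}:{lineno}: Feature declared before any Genome")
                model.genome_entries[-1][1].append(value)
                current = None
            elif key_n == "link":
                parts = value.split()
                if len(parts) != 3:
                    raise ConfigError(
                        f"{path}:{lineno}: Link needs 'path genomeA genomeB', "
                        f"got {value!r}")
                try:
                    ga, gb = int(parts[1]), int(parts[2])
                except ValueError:
                    raise ConfigError(
                        f"{path}:{lineno}: Link genome indices must be integers"
                    ) from None
                model.link_entries.append((parts[0], (ga, gb)))
                current = None
            elif key_n == "setparafor":
                scope = _parse_scope(value)
                current = AttrMap()
                model.blocks.append((scope, current))
            else:
                if current is None:
                    raise ConfigError(
                        f"{path}:{lineno}: parameter {key.strip()!r} outside a "
                        "SetParaFor block")
                current.set(key_n, value)

    model.validate()
    for p, _ in model.link_entries:
        if not model.resolve_path(p).exists():
            raise ConfigError(f"link file not found: {model.resolve_path(p)}")
    for p, featpaths in model.genome_entries:
        if not model.resolve_path(p).exists():
            raise ConfigError(f"genome file not found: {model.resolve_path(p)}")
        for fp in featpaths:
            if not model.resolve_path(fp).exists():
                raise ConfigError(f"feature file not found: {model.resolve_path(fp)}")
    return model


# ---------------------------------------------------------------------------
# cascade resolution

def _apply_layers(defaults, keymap, layers, what: str):
    values: dict[str, object] = {}
    extra: dict[str, str] = {}
    for scope, attrs in layers:
        for key, raw in attrs.items():
            entry = keymap.get(_norm_key(key))
            if entry is None:
                logger.warning("unknown parameter %r in %s block, kept as-is",
                               key, what)
                extra[key] = raw
                continue
            field_name, conv = entry
            values[field_name] = conv(raw, key)
    if extra:
        values["extra"] = tuple(sorted(extra.items()))
    return replace(defaults, **values)


def _scope_rank_genome(scope: ScopeId, genome_index: int) -> int | None:
    if scope.kind == ScopeKind.GLOBAL:
        return 0
    if scope.kind == ScopeKind.GENOME_ALL:
        return 1
    if scope.kind == ScopeKind.GENOME_N and scope.index == genome_index:
        return 2
    return None


def resolve_genome_params(model: ConfigModel, genome_index: int) -> GenomeParams:
    """Resolve effective parameters for genome *genome_index* (1-based)."""
    if not (1 <= genome_index <= model.n_genomes):
        raise ConfigError(f"genome index {genome_index} not declared")
    layers = []
    for rank in (0, 1, 2):
        for scope, attrs in model.blocks:
            if _scope_rank_genome(scope, genome_index) == rank:
                layers.append((scope, attrs))
    return _apply_layers(GenomeParams(), _GENOME_KEYS, layers,
                         f"Genome{genome_index}")


def resolve_link_params(model: ConfigModel, link_index: int) -> LinkParams:
    """Resolve effective parameters for link set *link_index* (1-based)."""
    if not (1 <= link_index <= model.n_links):
        raise ConfigError(f"link index {link_index} not declared")
    layers = []
    for want in (ScopeKind.GLOBAL, ScopeKind.LINK_N):
        for scope, attrs in model.blocks:
            if scope.kind != want:
                continue
            if want == ScopeKind.LINK_N and scope.index != link_index:
                continue
            # global blocks may mix genome and link keys; filter to link vocab
            layers.append((scope, attrs))
    filtered = []
    for scope, attrs in layers:
        keep = AttrMap()
        for k, v in attrs.items():
            if _norm_key(k) in _LINK_KEYS or scope.kind == ScopeKind.LINK_N:
                keep.set(k, v)
        filtered.append((scope, keep))
    return _apply_layers(LinkParams(), _LINK_KEYS, filtered, f"Link{link_index}")


def effective_link_params(params: LinkParams, attrs: AttrMap) -> LinkParams:
    """Overlay a single record's attributes on resolved link parameters."""
    values: dict[str, object] = {}
    for key, raw in attrs.items():
        entry = _LINK_KEYS.get(_norm_key(key))
        if entry is None:
            continue  # non-style attrs (e.g. svtype) are informational
        field_name, conv = entry
        values[field_name] = conv(raw, key)
    return replace(params, **values) if values else params


def dump_resolved_config(model: ConfigModel) -> str:
    """Emit fully resolved parameters per genome/link set as key=value text."""
    out: list[str] = []
    for i in range(1, model.n_genomes + 1):
        out.append(f"SetParaFor=Genome{i}")
        gp = resolve_genome_params(model, i)
        for f in fields(GenomeParams):
            if f.name == "extra":
                for k, v in gp.extra:
                    out.append(f"{k}={v}")
                continue
            val = getattr(gp, f.name)
            if f.name == "zoom_region" and val is not None:
                val = f"{val.seq_id}:{val.start}:{val.end}"
            out.append(f"{f.name}={val}")
        out.append("")
    for i in range(1, model.n_links + 1):
        out.append(f"SetParaFor=Link{i}")
        lp = resolve_link_params(model, i)
        for f in fields(LinkParams):
            if f.name == "extra":
                for k, v in lp.extra:
                    out.append(f"{k}={v}")
                continue
            out.append(f"{f.name}={getattr(lp, f.name)}")
        out.append("")
    return "\n".join(out)
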