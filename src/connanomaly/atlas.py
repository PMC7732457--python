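"""Brain atlas model: regions, metadata, and deterministic edge classification.

The default atlas is the HCP-MMP1 cortical parcellation (180 parcels per
hemisphere) plus 19 subcortical structures (9 per hemisphere and the brain
stem), 379 regions in total. Region order is fixed and shared by every
connectivity matrix in a run. Lobe and large-scale-network assignments are
read from a bundled metadata table, which callers may override with their
own file of the same layout.
"""
from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


class Hemisphere(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"


class RegionKind(str, enum.Enum):
    CORTICAL = "cortical"
    SUBCORTICAL = "subcortical"


class SubcorticalClass(str, enum.Enum):
    NONE = "none"
    BASAL_GANGLIA = "basal_ganglia"
    THALAMUS = "thalamus"
    HIPPOCAMPUS = "hippocampus"
    AMYGDALA = "amygdala"
    DIENCEPHALON = "diencephalon"
    CEREBELLUM = "cerebellum"
    BRAINSTEM = "brainstem"
    ACCUMBENS = "accumbens"


class HemisphereRelation(str, enum.Enum):
    """Laterality of an edge: within-left, within-right, crossing, or touching midline."""

    LEFT = "left"
    RIGHT = "right"
    BILATERAL = "bilateral"
    MIDLINE_INVOLVED = "midline_involved"


class Relationship(str, enum.Enum):
    """Anatomical class of an edge, mirroring the labels used in frequency tables."""

    INTRALOBAR = "intralobar"
    LONG_RANGE = "long_range"
    INTERHEMISPHERIC = "interhemispheric"
    CORTICOBASAL = "corticobasal"
    CORTICOTHALAMIC = "corticothalamic"
    CORTICOHIPPOCAMPAL = "corticohippocampal"
    CORTICO_SUBCORTICAL_OTHER = "cortico_subcortical_other"
    SUBCORTICO_SUBCORTICAL = "subcortico_subcortical"


@dataclass(frozen=True)
class Region:
    name: str
    hemisphere: Hemisphere
    kind: RegionKind
    subcortical_class: SubcorticalClass
    lobe: str
    network: str


@dataclass(frozen=True)
class EdgeClass:
    hemisphere_relation: HemisphereRelation
    relationship: Relationship


DEFAULT_N_REGIONS = 379
_DEFAULT_METADATA = "atlas_hcpmmp1_subcortical.tsv"
_COLUMNS = ("name", "hemisphere", "kind", "subcortical_class", "lobe", "network")


class AtlasError(ValueError):
    """Malformed atlas metadata or an unknown region/label."""


class Atlas:
    """Ordered collection of regions; order defines matrix row/column order."""

    def __init__(self, regions: Sequence[Region]):
        names = [r.name for r in regions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise AtlasError(f"duplicate region names: {dupes}")
        self.regions: tuple[Region, ...] = tuple(regions)
        self.index: dict[str, int] = {r.name: i for i, r in enumerate(self.regions)}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def region(self, name: str) -> Region:
        try:
            return self.regions[self.index[name]]
        except KeyError:
            raise AtlasError(f"unknown region {name!r}") from None

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.network)
        return list(seen)

    def validate_default_counts(self) -> None:
        """Check the 379-region invariant: 180 cortical per hemisphere + 19 subcortical."""
        cortical = [r for r in self.regions if r.kind is RegionKind.CORTICAL]
        subcortical = [r for r in self.regions if r.kind is RegionKind.SUBCORTICAL]
        left = sum(1 for r in cortical if r.hemisphere is Hemisphere.LEFT)
        right = sum(1 for r in cortical if r.hemisphere is Hemisphere.RIGHT)
        if not (len(self) == DEFAULT_N_REGIONS and left == right == 180
                and len(subcortical) == 19):
            raise AtlasError(
                f"default atlas must have 180+180 cortical and 19 subcortical "
                f"regions; got {left} left, {right} right, {len(subcortical)} subcortical"
            )
        midline = [r for r in self.regions if r.hemisphere is Hemisphere.MIDLINE]
        if [r.name for r in midline] != ["Brain stem"]:
            raise AtlasError("'Brain stem' must be the only midline region")


def _parse_region(parts: dict[str, str], lineno: int) -> Region:
    try:
        return Region(
            name=parts["name"],
            hemisphere=Hemisphere(parts["hemisphere"]),
            kind=RegionKind(parts["kind"]),
            subcortical_class=SubcorticalClass(parts["subcortical_class"]),
            lobe=parts["lobe"],
            network=parts["network"],
        )
    except ValueError as exc:
        raise AtlasError(f"line {lineno}: {exc}") from None


def load_atlas(metadata_path: str | Path, *, delimiter: str = "\t",
               expect_default: bool | None = None) -> Atlas:
    """Load an atlas from a delimited metadata table.

    Parameters
    ----------
    metadata_path
        UTF-8 text with one header line and columns
        name, hemisphere, kind, subcortical_class, lobe, network.
    expect_default
        If True, validate the 379-region default-atlas counts. If None,
        validate only when the file has exactly 379 rows.
    """
    path = Path(metadata_path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise AtlasError(f"{path}: empty metadata file")
    header = lines[0].split(delimiter)
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise AtlasError(f"{path}: line 1: missing columns {missing}")
    col = {c: header.index(c) for c in _COLUMNS}
    regions = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        if len(fields) < len(header):
            raise AtlasError(f"{path}: line {lineno}: expected {len(header)} fields")
        regions.append(_parse_region({c: fields[i] for c, i in col.items()}, lineno))
    atlas = Atlas(regions)
    if expect_default or (expect_default is None and len(atlas) == DEFAULT_N_REGIONS):
        atlas.validate_default_counts()
    return atlas


def default_atlas() -> Atlas:
    """The bundled 379-region atlas."""
    ref = importlib.resources.files("connanomaly.data") / _DEFAULT_METADATA
    with importlib.resources.as_file(ref) as path:
        return load_atlas(path, expect_default=True)


def classify_edge(atlas: Atlas, a: str, b: str) -> EdgeClass:
    """Classify the unordered edge {a, b} by laterality and anatomical relationship.

    Relationship priority: edges between two subcortical structures are
    subcortico-subcortical; edges with one subcortical endpoint are named for
    that structure (basal ganglia / accumbens -> corticobasal, thalamus ->
    corticothalamic, hippocampus -> corticohippocampal, otherwise
    cortico-subcortical); purely cortical edges are interhemispheric when the
    hemispheres differ, intralobar within one lobe, and long-range otherwise.
    Symmetric in its region arguments.
    """
    if a == b:
        raise AtlasError(f"self-edge ({a!r}, {b!r}) is undefined")
    ra, rb = atlas.region(a), atlas.region(b)

    if Hemisphere.MIDLINE in (ra.hemisphere, rb.hemisphere):
        hemi = HemisphereRelation.MIDLINE_INVOLVED
    elif ra.hemisphere is rb.hemisphere:
        hemi = HemisphereRelation(ra.hemisphere.value)
    else:
        hemi = HemisphereRelation.BILATERAL

    classes = {ra.subcortical_class, rb.subcortical_class}
    n_sub = sum(r.kind is RegionKind.SUBCORTICAL for r in (ra, rb))
    if n_sub == 2:
        rel = Relationship.SUBCORTICO_SUBCORTICAL
    elif classes & {SubcorticalClass.BASAL_GANGLIA, SubcorticalClass.ACCUMBENS}:
        rel = Relationship.CORTICOBASAL
    elif SubcorticalClass.THALAMUS in classes:
        rel = Relationship.CORTICOTHALAMIC
    elif SubcorticalClass.HIPPOCAMPUS in classes:
        rel = Relationship.CORTICOHIPPOCAMPAL
    elif n_sub == 1:
        rel = Relationship.CORTICO_SUBCORTICAL_OTHER
    elif ra.hemisphere is not rb.hemisphere:
        rel = Relationship.INTERHEMISPHERIC
    elif ra.lobe == rb.lobe:
        rel = Relationship.INTRALOBAR
    else:
        rel = Relationship.LONG_RANGE
    return EdgeClass(hemisphere_relation=hemi, relationship=rel)


def network_members(atlas: Atlas, network: str) -> list[str]:
    """Names of all regions affiliated with `network`, in atlas order."""
    members = [r.name for r in atlas.regions if r.network == network]
    if not members:
        raise AtlasError(
            f"unknown network {network!r}; available: {sorted(set(atlas.networks))}"
        )
    return members


def make_atlas(rows: Iterable[tuple[str, str, str, str, str, str]]) -> Atlas:
    """Build an atlas from (name, hemisphere, kind, subcortical_class, lobe, network)
    tuples; convenience for tests and synthetic cohorts."""
    return Atlas([_parse_region(dict(zip(_COLUMNS, row)), i + 1)
                  for i, row in enumerate(rows)])
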