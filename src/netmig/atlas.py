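"""The 379-region parcellation scheme and its large-scale-network map.

The package's coordinate system is a fixed registry of 379 brain regions:
180 cortical parcels per hemisphere (multimodal-parcellation short codes),
9 subcortical structures per hemisphere, and the brainstem as one midline
parcel.  Every region carries exactly one large-scale-network affiliation
label; ``Unassigned`` is a permitted label for parcels without a confident
affiliation.  All downstream matrices (functional connectivity, structural
streamline counts) are indexed in registry order, i.e. by ``region_id``
1..379.

The packaged default table honors the membership statements of the source
network scheme (a 15-region left-lateralised Language network, a 4-region
left Accessory Language network, area 23c in the Salience network, and the
stated default-mode / central-executive memberships); remaining parcels
follow a Yeo-style assignment, with the four largest systems (Visual,
Sensorimotor, DMN, CEN) deliberately equal in size so that raw per-network
tallies are comparable among them.  Any analysis accepts a user-supplied
table instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .errors import RegionLookupError, ValidationError

N_REGIONS = 379
N_CORTICAL_PER_HEMI = 180
N_SUBCORTICAL_PER_HEMI = 9

NETWORK_LABELS = (
    "CEN",
    "DMN",
    "DAN",
    "Limbic",
    "Salience",
    "Sensorimotor",
    "Visual",
    "Language",
    "AccessoryLanguage",
    "Auditory",
    "MultipleDemand",
    "VAN",
    "MedialTemporal",
    "Unassigned",
)

_HEMISPHERES = ("left", "right", "midline")
_KINDS = ("cortical", "subcortical", "brainstem")


@dataclass(frozen=True)
class Region:
    """One parcel: id, short name, hemisphere, tissue kind, network label."""

    region_id: int
    name: str
    hemisphere: str
    kind: str
    network: str

    def __post_init__(self):
        if self.hemisphere not in _HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown region kind {self.kind!r}")
        if self.network not in NETWORK_LABELS:
            raise ValidationError(f"unknown network label {self.network!r}")


class AtlasRegistry:
    """Ordered collection of the 379 regions with id/name lookup.

    Regions are stored in ascending ``region_id`` order; positional index
    ``i`` corresponds to ``region_id == i + 1``.
    """

    def __init__(self, regions: Iterable[Region]):
        self.regions: tuple[Region, ...] = tuple(
            sorted(regions, key=lambda r: r.region_id)
        )
        self._validate()
        self._by_id = {r.region_id: r for r in self.regions}
        self._by_name = {r.name: r for r in self.regions}

    def _validate(self) -> None:
        if len(self.regions) != N_REGIONS:
            raise ValidationError(
                f"registry must contain exactly {N_REGIONS} regions, "
                f"got {len(self.regions)}"
            )
        ids = [r.region_id for r in self.regions]
        if ids != list(range(1, N_REGIONS + 1)):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise ValidationError(f"duplicate region_id(s): {sorted(dupes)}")
            raise ValidationError("region_id values must be contiguous 1..379")
        names = [r.name for r in self.regions]
        if len(set(names)) != N_REGIONS:
            raise ValidationError("region names must be unique")
        for hemi in ("left", "right"):
            n_cort = sum(
                1 for r in self.regions if r.hemisphere == hemi and r.kind == "cortical"
            )
            n_sub = sum(
                1
                for r in self.regions
                if r.hemisphere == hemi and r.kind == "subcortical"
            )
            if n_cort != N_CORTICAL_PER_HEMI:
                raise ValidationError(
                    f"expected {N_CORTICAL_PER_HEMI} cortical regions in "
                    f"{hemi} hemisphere, got {n_cort}"
                )
            if n_sub != N_SUBCORTICAL_PER_HEMI:
                raise ValidationError(
                    f"expected {N_SUBCORTICAL_PER_HEMI} subcortical regions in "
                    f"{hemi} hemisphere, got {n_sub}"
                )
        n_stem = sum(1 for r in self.regions if r.kind == "brainstem")
        if n_stem != 1:
            raise ValidationError(f"expected exactly 1 brainstem region, got {n_stem}")

    # -- lookup ----------------------------------------------------------

    def region(self, key: Union[int, str]) -> Region:
        """Resolve a region by ``region_id`` or by name."""
        if isinstance(key, (int,)):
            try:
                return self._by_id[key]
            except KeyError:
                raise RegionLookupError(f"no region with id {key}") from None
        try:
            return self._by_name[key]
        except KeyError:
            raise RegionLookupError(f"no region named {key!r}") from None

    def index_of(self, key: Union[int, str]) -> int:
        """0-based positional index of a region (matrix row/column)."""
        return self.region(key).region_id - 1

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __eq__(self, other) -> bool:
        return isinstance(other, AtlasRegistry) and self.regions == other.regions

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def networks(self) -> list[str]:
        """Network label per region, in registry order."""
        return [r.network for r in self.regions]

    def members(self, network: str) -> list[Region]:
        if network not in NETWORK_LABELS:
            raise ValidationError(f"unknown network label {network!r}")
        return [r for r in self.regions if r.network == network]

    def network_sizes(self) -> dict[str, int]:
        sizes = {n: 0 for n in NETWORK_LABELS}
        for r in self.regions:
            sizes[r.network] += 1
        return sizes


def network_of(registry: AtlasRegistry, region: Union[int, str]) -> str:
    """Return the network affiliation of a region (by name or id)."""
    return registry.region(region).network


def load_affiliation_table(path: Union[str, Path]) -> AtlasRegistry:
    """Read a region/network affiliation CSV into a validated registry.

    Expected header: ``region_id,name,hemisphere,kind,network``.
    """
    regions = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"region_id", "name", "hemisphere", "kind", "network"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"affiliation table must have columns {sorted(required)}"
            )
        for row in reader:
            try:
                rid = int(row["region_id"])
            except ValueError:
                raise ValidationError(
                    f"non-integer region_id {row['region_id']!r}"
                ) from None
            regions.append(
                Region(
                    region_id=rid,
                    name=row["name"],
                    hemisphere=row["hemisphere"],
                    kind=row["kind"],
                    network=row["network"],
                )
            )
    return AtlasRegistry(regions)


def write_affiliation_table(registry: AtlasRegistry, path: Union[str, Path]) -> None:
    """Write a registry back to the affiliation CSV format (ids ascending)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region_id", "name", "hemisphere", "kind", "network"])
        for r in registry:
            writer.writerow([r.region_id, r.name, r.hemisphere, r.kind, r.network])


def build_default_atlas() -> AtlasRegistry:
    """Load the packaged default 379-region affiliation table."""
    ref = resources.files("netmig.data").joinpath("default_affiliations.csv")
    with resources.as_file(ref) as path:
        return load_affiliation_table(path)
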