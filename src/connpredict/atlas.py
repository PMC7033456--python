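"""ROI sets and network definitions.

All networks used in the analyses are drawn from a pool of 198 spherical
regions of interest (5 mm radius) defined by MNI coordinates: 196 cortical
atlas ROIs plus a left/right amygdala pair. Networks are named subsets of
the pool: ten canonical resting-state networks (visual, fronto-parietal,
somatomotor, dorsal/ventral attention, salience, memory retrieval,
cingulo-opercular, default mode, subcortical) and two theory-driven sets —
a "resonance" network (shared representation / imitation circuitry:
inferior frontal gyrus, somatomotor cortex, insula, amygdala, STS, parietal
areas) and a "control" network (prefrontal and temporoparietal regions
implicated in top-down regulation of resonance).

Packaged fixtures
-----------------
``table1_resonance_control.tsv``
    The 34 resonance + 22 control ROIs with their published MNI
    coordinates.
``pool_198_synthetic.tsv``
    A 198-ROI pool with canonical network labels at the published
    per-network sizes. The 56 resonance/control coordinates are real; the
    remaining 142 rows are synthetic stand-in coordinates (the canonical
    atlas membership table is not redistributed here), so this fixture
    supports counting, pooling, sham sampling and simulation but is not an
    anatomical reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateRoiError,
    InvalidNetworkError,
    ParseError,
    SamplingError,
    SchemaError,
)

__all__ = [
    "Roi",
    "RoiSet",
    "NetworkDefinition",
    "load_roi_table",
    "load_table1",
    "load_pool198",
    "build_network",
    "pool_networks",
    "sample_sham_network",
]

_REQUIRED_COLUMNS = ("region_name", "network", "x_mm", "y_mm", "z_mm")


@dataclass(frozen=True)
class Roi:
    """A spherical region of interest centred on an MNI coordinate (mm, RAS)."""

    region_name: str
    atlas_id: int | None
    network: str
    x: float
    y: float
    z: float
    radius: float = 5.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.x, self.y, self.z]).all():
            raise ParseError(f"non-finite coordinates for ROI {self.region_name!r}")
        if self.radius <= 0:
            raise ParseError(f"radius must be positive, got {self.radius}")

    @property
    def label(self) -> str:
        """Stable string identifier used for time-course rows and edge labels."""
        if self.atlas_id is not None:
            return f"roi{self.atlas_id:03d}"
        side = "L" if self.x < 0 else "R"
        return f"{self.region_name.lower().replace(' ', '_')}_{side}"

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class RoiSet:
    """An ordered collection of unique ROIs."""

    def __init__(self, rois: Iterable[Roi]):
        self.rois: list[Roi] = list(rois)
        keys = [(r.network, r.atlas_id if r.atlas_id is not None else (r.x, r.y, r.z))
                for r in self.rois]
        if len(set(keys)) != len(keys):
            raise DuplicateRoiError("duplicate ROI (network, id/coordinates) in set")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self) -> Iterator[Roi]:
        return iter(self.rois)

    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rois:
            seen.setdefault(r.network, None)
        return list(seen)

    def subset(self, network: str) -> "RoiSet":
        return RoiSet([r for r in self.rois if r.network == network])

    def labels(self) -> list[str]:
        return [r.label for r in self.rois]


@dataclass(frozen=True)
class NetworkDefinition:
    """A named, ordered ROI collection admitting at least one edge.

    The ROI order is part of the definition: it fixes the row order of
    extracted time courses and hence the edge order of downstream feature
    vectors.
    """

    name: str
    rois: tuple[Roi, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.rois) < 2:
            raise InvalidNetworkError(
                f"network {self.name!r} has {len(self.rois)} ROI(s); need >= 2"
            )

    @property
    def n(self) -> int:
        return len(self.rois)

    @property
    def n_edges(self) -> int:
        return self.n * (self.n - 1) // 2

    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    def coordinates(self) -> np.ndarray:
        return np.array([[r.x, r.y, r.z] for r in self.rois], dtype=float)


def load_roi_table(path, dialect: str = "default") -> RoiSet:
    """Load an ROI table (TSV) into a :class:`RoiSet`.

    Parameters
    ----------
    path : str or Path
        Tab-separated table with columns region_name, atlas_id (may be
        empty), network, x_mm, y_mm, z_mm.
    dialect : str
        Table schema identifier; only ``"default"`` is defined.
    """
    if dialect != "default":
        raise SchemaError(f"unknown ROI-table dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty ROI table: {path}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ROI table {path} missing columns: {missing}")
    rois = []
    for _, rec in df.iterrows():
        aid_raw = rec.get("atlas_id")
        atlas_id: int | None
        if aid_raw is None or (isinstance(aid_raw, float) and np.isnan(aid_raw)) \
                or str(aid_raw).strip() in ("", "nan", "N/A", "NA"):
            atlas_id = None
        else:
            try:
                atlas_id = int(float(aid_raw))
            except ValueError as exc:
                raise ParseError(f"non-integer atlas_id {aid_raw!r}") from exc
        try:
            x, y, z = (float(rec[c]) for c in ("x_mm", "y_mm", "z_mm"))
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"non-numeric coordinate in row {rec['region_name']!r}"
            ) from exc
        rois.append(Roi(str(rec["region_name"]), atlas_id, str(rec["network"]), x, y, z))
    return RoiSet(rois)


def _packaged(name: str):
    return resources.files("connpredict").joinpath("data", name)


def load_table1() -> RoiSet:
    """The packaged resonance (34 ROIs) + control (22 ROIs) table."""
    with resources.as_file(_packaged("table1_resonance_control.tsv")) as p:
        return load_roi_table(p)


def load_pool198() -> RoiSet:
    """The packaged 198-ROI pool with canonical network labels (synthetic
    stand-in coordinates outside the resonance/control table)."""
    with resources.as_file(_packaged("pool_198_synthetic.tsv")) as p:
        return load_roi_table(p)


def _ordering_key(roi: Roi):
    # Atlas-id ascending; ROIs without an id (amygdala) sort last,
    # left hemisphere before right.
    if roi.atlas_id is not None:
        return (0, roi.atlas_id, 0.0)
    return (1, 0, roi.x)


def build_network(rois: RoiSet, name: str) -> NetworkDefinition:
    """Build a named network from all ROIs in `rois` carrying that label.

    ROI order is deterministic: ascending atlas id, with id-less ROIs
    (the amygdala pair) appended last, left before right.
    """
    members = [r for r in rois if r.network == name]
    if len(members) < 2:
        raise InvalidNetworkError(
            f"network {name!r} has {len(members)} ROI(s) in this table; need >= 2"
        )
    members.sort(key=_ordering_key)
    return NetworkDefinition(name=name, rois=tuple(members))


def pool_networks(a: NetworkDefinition, b: NetworkDefinition) -> NetworkDefinition:
    """Pool two disjoint networks into one (a's ROIs first, then b's).

    Pooling treats the aggregate as a single network so that the feature
    set contains all pairwise edges within and across both networks.
    """
    keys_a = {(r.x, r.y, r.z) for r in a.rois}
    overlap = [r for r in b.rois if (r.x, r.y, r.z) in keys_a]
    if overlap:
        raise DuplicateRoiError(
            f"networks {a.name!r} and {b.name!r} share {len(overlap)} ROI(s)"
        )
    return NetworkDefinition(name=f"{a.name}+{b.name}", rois=a.rois + b.rois)


def sample_sham_network(
    pool: RoiSet | Sequence[Roi],
    size: int,
    seed: int | np.random.Generator,
    name: str | None = None,
) -> NetworkDefinition:
    """Draw a size-matched sham network from the pool without replacement.

    Sham membership ignores functional labels entirely; the draw order is
    the network's ROI order and is fully determined by `seed`.
    """
    rois = list(pool)
    if size < 2:
        raise InvalidNetworkError(f"sham size {size} < 2")
    if size > len(rois):
        raise SamplingError(f"sham size {size} exceeds pool of {len(rois)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(rois), size=size, replace=False)
    members = tuple(replace(rois[i], network="sham") for i in idx)
    return NetworkDefinition(name=name or f"sham{size}", rois=members)
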