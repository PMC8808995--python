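"""Marker panel definitions for cyclic multiplex IHC of glia.

A panel lists every imaged channel together with its role:

* ``constitutive`` — the channel that defines a cell type's profiles and
  drives segmentation (ALDH1L1 for astrocytes, IBA1 for microglia);
* ``phenotypic`` — markers whose mean gray intensity (MGI) is measured
  within each segmented profile;
* ``lesion`` — channels carrying Alzheimer lesions (Aβ plaques, PHF1+
  neurofibrillary tangles) used as spatial reference objects;
* ``nuclear`` — DAPI.

TSPO is expressed by both astrocytes and microglia and therefore carries
``cell_type='both'``: it is measured within profiles of either cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ROLES = ("constitutive", "phenotypic", "lesion", "nuclear")
CELL_TYPES = ("astrocyte", "microglia", "both", "neuron", "lesion")


@dataclass(frozen=True)
class Marker:
    name: str
    role: str
    cell_type: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for marker {self.name}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r} for marker {self.name}")


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered collection of markers with role/cell-type bookkeeping."""

    markers: tuple[Marker, ...] = field(default_factory=tuple)

    def __post_init__(self):
        names = [m.name for m in self.markers]
        if len(names) != len(set(names)):
            raise ValueError("marker names must be unique")
        for ct in ("astrocyte", "microglia"):
            n_const = sum(
                1 for m in self.markers if m.role == "constitutive" and m.cell_type == ct
            )
            if n_const != 1:
                raise ValueError(f"panel needs exactly one constitutive marker for {ct}s, got {n_const}")

    def __iter__(self):
        return iter(self.markers)

    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def constitutive(self, cell_type: str) -> str:
        for m in self.markers:
            if m.role == "constitutive" and m.cell_type == cell_type:
                return m.name
        raise KeyError(cell_type)

    def phenotypic(self, cell_type: str) -> list[str]:
        """Phenotypic markers measured for a cell type (includes 'both')."""
        return sorted(
            m.name
            for m in self.markers
            if m.role == "phenotypic" and m.cell_type in (cell_type, "both")
        )

    def lesion_channel(self, lesion_type: str) -> str:
        mapping = {"plaque": "Abeta", "NFT": "PHF1"}
        name = mapping[lesion_type]
        if name not in self.names():
            raise KeyError(f"panel lacks lesion channel {name}")
        return name


def default_panel() -> MarkerPanel:
    """The glial phenotyping panel: 7 astrocytic + 5 microglial markers
    (TSPO shared), two constitutive channels, two lesion channels, DAPI."""
    return MarkerPanel(
        markers=(
            Marker("ALDH1L1", "constitutive", "astrocyte"),
            Marker("IBA1", "constitutive", "microglia"),
            Marker("EAAT1", "phenotypic", "astrocyte"),
            Marker("EAAT2", "phenotypic", "astrocyte"),
            Marker("GFAP", "phenotypic", "astrocyte"),
            Marker("GS", "phenotypic", "astrocyte"),
            Marker("VIM", "phenotypic", "astrocyte"),
            Marker("YKL-40", "phenotypic", "astrocyte"),
            Marker("TSPO", "phenotypic", "both"),
            Marker("CD68", "phenotypic", "microglia"),
            Marker("FTL", "phenotypic", "microglia"),
            Marker("MHC2", "phenotypic", "microglia"),
            Marker("TMEM119", "phenotypic", "microglia"),
            Marker("Abeta", "lesion", "lesion"),
            Marker("PHF1", "lesion", "lesion"),
            Marker("DAPI", "nuclear", "neuron"),
        )
    )


#: Markers whose elevation defines glial reactivity; used to rank clusters
#: into homeostatic < intermediate < reactive.
REACTIVE_PANEL = {
    "astrocyte": ("GFAP", "VIM", "YKL-40", "TSPO"),
    "microglia": ("CD68", "MHC2", "TSPO", "FTL"),
}

STATE_NAMES = ("homeostatic", "intermediate", "reactive")
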