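"""Catalog of morphological landmark events in Drosophila embryogenesis.

The pipeline stages embryos against an ordered list of 36 visually
recognizable morphological transitions, from the appearance of the
posterior gap shortly after egg deposition through hatching.  Two of
these serve as timing anchors: completion of cellularization ("membrane
reaches yolk"), the zero time-point, and tracheal filling, the unit
time-point.  Eight events (the anchors plus six others identifiable
regardless of embryo orientation) are flagged as primary and carry the
bulk of the quantitative analysis; hatching is retained in the catalog
but excluded from scaling statistics because its timing is dominated by
assay conditions rather than developmental state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Event",
    "EventCatalog",
    "DEFAULT_CATALOG",
    "ANCHOR_START",
    "ANCHOR_END",
]

#: Event used as the zero time-point (end of cellularization).
ANCHOR_START = "membrane_reaches_yolk"
#: Event used as the unit time-point (tracheal filling).
ANCHOR_END = "trachea_fills"


@dataclass(frozen=True)
class Event:
    """One morphological landmark.

    Parameters
    ----------
    name :
        Machine-friendly identifier (snake_case).
    label :
        Human-readable name as used in the embryology literature.
    stage :
        Canonical embryonic stage number the event falls in.
    primary :
        Whether the event belongs to the set of eight unambiguous
        landmarks identifiable from any embryo orientation.
    anchor :
        Whether the event is one of the two timing anchors.
    """

    name: str
    label: str
    stage: int
    primary: bool = False
    anchor: bool = False


def _ev(name: str, label: str, stage: int, primary: bool = False,
        anchor: bool = False) -> Event:
    return Event(name=name, label=label, stage=stage, primary=primary,
                 anchor=anchor)


_EVENTS: tuple[Event, ...] = (
    _ev("posterior_gap_appears", "Posterior gap appears", 2),
    _ev("pole_bud_appears", "Pole bud appears", 3, primary=True),
    _ev("nuclei_at_periphery", "Nuclei at periphery", 4),
    _ev("pole_cells_form", "Pole cells form", 4),
    _ev("yolk_contraction", "Yolk contraction", 4),
    _ev("cellularization_begins", "Cellularization begins", 5),
    _ev(ANCHOR_START, "Membrane reaches the yolk", 5, primary=True,
        anchor=True),
    _ev("pole_cells_migrate", "Pole cells migrate", 6),
    _ev("cephalic_furrow_forms", "Cephalic furrow forms", 6),
    _ev("pole_cells_invaginate", "Pole cells invaginate", 7, primary=True),
    _ev("transversal_fold_formation", "Transversal fold formation", 7),
    _ev("cephalic_furrow_reclines", "Cephalic furrow reclines", 8),
    _ev("amnioproctodeal_invagination", "Amnioproctodeal invagination", 8,
        primary=True),
    _ev("anterior_midgut_primordial", "Anterior midgut primordial", 8),
    _ev("stomodeal_plate_forms", "Stomodeal plate forms", 9),
    _ev("stomodeum_invagination", "Stomodeum invagination", 10),
    _ev("clypeolabral_lobe_forms", "Clypeolabral lobe forms", 10),
    _ev("germ_band_maxima", "Germ band maxima", 11),
    _ev("clypeolabrum_rotates", "Clypeolabrum rotates", 11),
    _ev("posterior_gap", "Posterior gap", 11),
    _ev("gnathal_bud_appears", "Gnathal bud appears", 12),
    _ev("germband_retraction_begins", "Germband retraction begins", 12),
    _ev("amnioserosa_exposed", "Amnioserosa exposed", 12, primary=True),
    _ev("germband_retracted", "Germband retracted", 13),
    _ev("dorsal_divot", "Dorsal divot", 14),
    _ev("clypeolabrum_retracts", "Clypeolabrum retracts", 14, primary=True),
    _ev("anal_plate_forms", "Anal plate forms", 14),
    _ev("midgut_unified", "Midgut unified", 14),
    _ev("heart_shaped_midgut", "Heart-shaped midgut", 15, primary=True),
    _ev("clypeolabrum_even_with_ventral_lobes",
        "Clypeolabrum even with ventral lobes", 16),
    _ev("gnathal_lobes_pinch", "Gnathal lobes pinch", 16),
    _ev("convoluted_gut", "Convoluted gut", 16),
    _ev("head_involution_done", "Head involution done", 17),
    _ev("muscle_contractions", "Muscle contractions", 17),
    _ev(ANCHOR_END, "Trachea fills", 17, primary=True, anchor=True),
    _ev("hatch", "Hatch", 17),
)


@dataclass(frozen=True)
class EventCatalog:
    """Ordered catalog of developmental landmark events.

    Order is developmental order; all staging and timing code relies on
    it when validating calls and proportions.
    """

    events: tuple[Event, ...] = field(default=_EVENTS)

    def __post_init__(self) -> None:
        names = [e.name for e in self.events]
        if len(set(names)) != len(names):
            raise ValueError("duplicate event names in catalog")
        anchors = [e.name for e in self.events if e.anchor]
        if anchors != [ANCHOR_START, ANCHOR_END]:
            raise ValueError(
                "catalog must contain exactly the two anchors in order")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    @property
    def index(self) -> dict[str, int]:
        """Map event name -> position in developmental order."""
        return {e.name: i for i, e in enumerate(self.events)}

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.events]

    @property
    def primary_names(self) -> list[str]:
        return [e.name for e in self.events if e.primary]

    def order(self, name: str) -> int:
        try:
            return self.index[name]
        except KeyError:
            raise KeyError(f"unknown event {name!r}") from None

    def validate_names(self, names) -> None:
        """Raise ``ValueError`` naming the first unknown event, if any."""
        idx = self.index
        for n in names:
            if n not in idx:
                raise ValueError(f"unknown event {n!r}")

    def in_order(self, names) -> bool:
        """True if ``names`` respect developmental order."""
        orders = [self.order(n) for n in names]
        return all(a < b for a, b in zip(orders, orders[1:]))


#: Module-level default: the full 36-event catalog.
DEFAULT_CATALOG = EventCatalog()
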