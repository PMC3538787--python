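"""Binary dummy-variable design matrices shared by the regression and the network.

Two fixed configurations are used:

* FD configuration (``drop_base=True, interactions=True, intercept=True``):
  one indicator per non-base species and non-base event, two
  primate-by-event-class interaction columns (primate x cortical,
  primate x limbic) and an intercept — (s-1) + (e-1) + 2 + 1 = s + e + 1
  columns. Dropping a base species and base event avoids the singularity
  of the full indicator coding.
* FFNN configuration (``drop_base=False, interactions=False,
  intercept=False``): all s + e indicators, nothing else. The network has
  its own biases, and weight decay handles the redundancy of the full
  coding, so every row sums to exactly 2 (one species, one event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .event_data import EventTimingTable


class UntrainableQueryError(KeyError):
    """Query names a species or event absent from the training design."""


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_obs, n_cols), entries in {0, 1}
    column_labels: list[str]
    species: list[str]  # all species the design knows, sorted
    events: list[str]
    base_species: str | None
    base_event: str | None
    interactions: bool
    intercept: bool
    primate_flags: dict = field(repr=False)  # species -> bool
    event_classes: dict = field(repr=False)  # event -> class
    obs_index: list = field(repr=False)  # row order: list of (species, event)

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def config(self) -> dict:
        return {
            "drop_base": self.base_species is not None,
            "base_species": self.base_species,
            "base_event": self.base_event,
            "interactions": self.interactions,
            "intercept": self.intercept,
        }


def build_design(
    table: EventTimingTable,
    drop_base: bool,
    base_species: str = "auto",
    base_event: str = "auto",
    interactions: bool = False,
    intercept: bool = False,
) -> DesignMatrix:
    """Build the binary predictor matrix for the table's known observations.

    Row order follows the table's observation order. Species columns come
    first, then event columns, then (optionally) the two primate-class
    interaction columns and the intercept. With ``drop_base`` the
    lexicographically first species/event is dropped unless an explicit
    base is named.
    """
    if table.n_observations == 0:
        raise ValueError("empty table")
    species = table.species
    events = table.events

    if drop_base:
        if base_species == "auto":
            base_species = species[0]
        if base_event == "auto":
            base_event = events[0]
        if base_species not in species:
            raise KeyError(f"base species {base_species!r} not in table")
        if base_event not in events:
            raise KeyError(f"base event {base_event!r} not in table")
        sp_cols = [s for s in species if s != base_species]
        ev_cols = [e for e in events if e != base_event]
    else:
        base_species = base_event = None
        sp_cols = list(species)
        ev_cols = list(events)

    primate_flags = {m.species: m.is_primate for m in table.species_meta()}
    event_classes = {m.event: m.event_class for m in table.event_meta()}

    labels = [f"species:{s}" for s in sp_cols] + [f"event:{e}" for e in ev_cols]
    if interactions:
        labels += ["primate_x_cortical", "primate_x_limbic"]
    if intercept:
        labels += ["intercept"]

    sp_pos = {s: i for i, s in enumerate(sp_cols)}
    ev_pos = {e: len(sp_cols) + j for j, e in enumerate(ev_cols)}

    df = table.data
    n = len(df)
    X = np.zeros((n, len(labels)))
    obs_index = []
    for row, rec in enumerate(df.itertuples()):
        obs_index.append((rec.species, rec.event))
        if rec.species in sp_pos:
            X[row, sp_pos[rec.species]] = 1.0
        if rec.event in ev_pos:
            X[row, ev_pos[rec.event]] = 1.0
    if interactions:
        base = len(sp_cols) + len(ev_cols)
        for row, rec in enumerate(df.itertuples()):
            if primate_flags[rec.species]:
                if event_classes[rec.event] == "cortical":
                    X[row, base] = 1.0
                elif event_classes[rec.event] == "limbic":
                    X[row, base + 1] = 1.0
    if intercept:
        X[:, -1] = 1.0

    return DesignMatrix(
        X=X,
        column_labels=labels,
        species=species,
        events=events,
        base_species=base_species,
        base_event=base_event,
        interactions=interactions,
        intercept=intercept,
        primate_flags=primate_flags,
        event_classes=event_classes,
        obs_index=obs_index,
    )


def encode_query(design: DesignMatrix, species: str, event: str) -> np.ndarray:
    """Encode a (species, event) query as a row consistent with the design.

    Raises :class:`UntrainableQueryError` for a species or event that was
    absent when the design was built — no coefficient exists for it.
    """
    if species not in design.species:
        raise UntrainableQueryError(f"species {species!r} was not in the training data")
    if event not in design.events:
        raise UntrainableQueryError(f"event {event!r} was not in the training data")
    x = np.zeros(design.n_cols)
    pos = {lab: i for i, lab in enumerate(design.column_labels)}
    sp_lab, ev_lab = f"species:{species}", f"event:{event}"
    if sp_lab in pos:  # base species encodes as all-zero species block
        x[pos[sp_lab]] = 1.0
    if ev_lab in pos:
        x[pos[ev_lab]] = 1.0
    if design.interactions and design.primate_flags[species]:
        cls = design.event_classes[event]
        if cls == "cortical":
            x[pos["primate_x_cortical"]] = 1.0
        elif cls == "limbic":
            x[pos["primate_x_limbic"]] = 1.0
    if design.intercept:
        x[pos["intercept"]] = 1.0
    return x


def fd_design(table: EventTimingTable, base_species: str = "auto",
              base_event: str = "auto") -> DesignMatrix:
    """The FD-model configuration: base dropping, interactions, intercept."""
    return build_design(table, drop_base=True, base_species=base_species,
                        base_event=base_event, interactions=True, intercept=True)


def ffnn_design(table: EventTimingTable) -> DesignMatrix:
    """The network configuration: all s+e indicators, no intercept."""
    return build_design(table, drop_base=False, interactions=False, intercept=False)
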