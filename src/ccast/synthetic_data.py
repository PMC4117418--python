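"""Labelled synthetic cytometry mixtures for end-to-end testing.

The generator draws, per mixture component and per marker, independent
normal intensities on the arcsinh scale, with qualitative levels mapped to
(mean, sd) pairs:

    low = (1, 0.3)   low-mid = (2, 0.3)   mid = (3, 0.3)   high = (5, 0.3)

A two-part level such as ``"low high"`` is an equal 50/50 mixture of the
two named levels (a bimodal marker within one component); explicit
``(mean, sd)`` pairs are also accepted.  The default design emulates a
five-state progression of 850 cells (component sizes 100/300/150/100/200)
measured on 3 markers, with marker 3 "high" in every component — hence
uninformative for gating — and an intermediate state adjacent to the
low/low state so their tails overlap and the initial gating tree has
mixed leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_cyto import ExpressionTable

__all__ = ["LEVELS", "Component", "SimSpec", "default_spec", "simulate"]

#: qualitative level -> (mean, sd) on the arcsinh scale
LEVELS: dict[str, tuple[float, float]] = {
    "low": (1.0, 0.3),
    "low-mid": (2.0, 0.3),
    "mid": (3.0, 0.3),
    "high": (5.0, 0.3),
}


def _resolve_level(level) -> list[tuple[float, float]]:
    """A level resolves to one normal or, for two-part levels, two."""
    if isinstance(level, str):
        parts = level.split()
        if not 1 <= len(parts) <= 2:
            raise ValueError(f"level {level!r} must name one or two levels")
        try:
            return [LEVELS[p] for p in parts]
        except KeyError as exc:
            raise ValueError(f"unknown level {exc} in {level!r}; known: {sorted(LEVELS)}")
    mean, sd = level
    if not sd > 0:
        raise ValueError(f"sd must be positive, got {sd}")
    return [(float(mean), float(sd))]


@dataclass(frozen=True)
class Component:
    size: int
    levels: tuple  # one entry per marker: level name or (mean, sd)

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("component size must be >= 1")
        for lev in self.levels:
            _resolve_level(lev)


@dataclass(frozen=True)
class SimSpec:
    components: tuple[Component, ...]
    markers: tuple[str, ...]
    seed: int = 0

    def __post_init__(self):
        for comp in self.components:
            if len(comp.levels) != len(self.markers):
                raise ValueError("every component needs one level per marker")

    @property
    def total_cells(self) -> int:
        return sum(c.size for c in self.components)


def default_spec(seed: int = 0) -> SimSpec:
    """Five-component, 3-marker, 850-cell progression design.

    Component sizes 100/300/150/100/200; markers 1-2 carry the structure
    while marker 3 is "high" everywhere — an always-on lineage marker that
    is uninformative for gating — so a correct tree uses only Marker1 and
    Marker2.  Four states occupy the corners of the (marker1, marker2)
    plane and the fifth is an intermediate (low-mid, mid) state whose
    tails overlap the low/low corner, giving the purification loop real
    contamination to remove while keeping every component resolvable by
    the mixture stage and every tree node's best marker and cut
    unambiguous (a reproducible gating hierarchy under resampling).
    """
    patterns = [
        (100, ("low", "low", "high")),
        (300, ("high", "high", "high")),
        (150, ("low", "high", "high")),
        (100, ("high", "low", "high")),
        (200, ("low-mid", "mid", "high")),
    ]
    return SimSpec(
        components=tuple(Component(size, levels) for size, levels in patterns),
        markers=("Marker1", "Marker2", "Marker3"),
        seed=seed,
    )


def simulate(spec: SimSpec) -> tuple[ExpressionTable, np.ndarray]:
    """Draw the mixture; returns the (transformed-scale) table and true labels.

    Sampling is per-component, so label counts equal the spec sizes
    exactly; deterministic given ``spec.seed``.  Component labels are
    0-based in spec order.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = []
    labels = []
    for j, comp in enumerate(spec.components):
        cols = []
        for lev in comp.levels:
            parts = _resolve_level(lev)
            if len(parts) == 1:
                (mean, sd), = parts
                cols.append(rng.normal(mean, sd, size=comp.size))
            else:
                pick = rng.integers(0, 2, size=comp.size)
                means = np.array([p[0] for p in parts])[pick]
                sds = np.array([p[1] for p in parts])[pick]
                cols.append(rng.normal(means, sds))
        blocks.append(np.column_stack(cols))
        labels.append(np.full(comp.size, j))
    table = ExpressionTable(
        values=np.vstack(blocks),
        marker_names=spec.markers,
        event_ids=np.arange(spec.total_cells),
        transformed=True,
    )
    return table, np.concatenate(labels)
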