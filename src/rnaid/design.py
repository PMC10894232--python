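"""Construct geometry for nanopore RNA identifiers (RNA IDs).

An RNA ID is an RNA transcript hybridized with short complementary DNA
oligos, a few of which carry streptavidin labels.  Two label kinds are
modelled: the tandem-repeats label ``R`` (two streptavidins, blocking
roughly twice the current of a single-streptavidin label) that marks the
start of each transcription cycle, and single-streptavidin ``1`` bits used
as positional fiducials.  An :class:`IDDesign` records where those labels
sit along the transcript (kbp from the 5' end), where the alternative
terminator inside the origin of replication (OriC) lies, and -- for
circular templates transcribed in a rolling-circle manner -- the cumulative
offset at which each transcription cycle begins.

The same geometry drives both the synthetic trace generator and the
spike-to-label matching used for calibration, so it lives in one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "LabelKind",
    "Topology",
    "LabelSpec",
    "IDDesign",
    "DesignError",
    "MissingFieldError",
    "LabelOrderError",
    "GeometryError",
    "load_design",
    "load_design_file",
    "load_fixture",
    "fixture_text",
    "layout_for_truth",
]


class LabelKind(str, Enum):
    """Kinds of streptavidin label rendered along an RNA ID."""

    R = "R"          # tandem-repeats label, two streptavidins (~2x depth)
    BIT1 = "BIT1"    # single-streptavidin positional "1" bit


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


class DesignError(ValueError):
    """Base class for RNA ID design validation failures."""


class MissingFieldError(DesignError):
    """A required configuration field is absent."""


class LabelOrderError(DesignError):
    """Label positions are not strictly increasing (unsorted or overlapping)."""


class GeometryError(DesignError):
    """Positions/termination points violate the construct geometry."""


@dataclass(frozen=True)
class LabelSpec:
    """One label: distance from the transcript 5' start (kbp) and its kind."""

    position_kbp: float
    kind: LabelKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", LabelKind(self.kind))
        object.__setattr__(self, "position_kbp", float(self.position_kbp))
        if self.position_kbp < 0:
            raise GeometryError(
                f"position_kbp: label position must be >= 0, got {self.position_kbp}"
            )


@dataclass(frozen=True)
class IDDesign:
    """Geometry of a construct's transcript and its label layout.

    Parameters
    ----------
    topology
        ``linear`` (run-off transcription from a linearized template) or
        ``circular`` (rolling-circle transcription of a plasmid).
    labels
        Within-cycle label layout, positions in kbp from the cycle start,
        strictly increasing.
    oric_term_offset_kbp
        Distance from a cycle start to the OriC premature-termination point.
    full_length_kbp
        Expected full-length (END) transcript length; linear designs only.
    cycle_starts_kbp
        Cumulative offsets at which successive transcription cycles begin
        (circular only); its length bounds the number of modelled cycles.
    """

    topology: Topology
    labels: tuple[LabelSpec, ...]
    oric_term_offset_kbp: float
    full_length_kbp: float | None = None
    cycle_starts_kbp: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "topology", Topology(self.topology))
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "cycle_starts_kbp", tuple(float(s) for s in self.cycle_starts_kbp))
        if not self.labels:
            raise MissingFieldError("labels: at least one label is required")
        pos = [lab.position_kbp for lab in self.labels]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise LabelOrderError(
                f"labels: positions must be strictly increasing (sorted, non-overlapping), got {pos}"
            )
        if self.oric_term_offset_kbp <= pos[-1]:
            raise GeometryError(
                "oric_term_offset_kbp: every label in a cycle must precede the "
                f"OriC termination point ({self.oric_term_offset_kbp} kbp <= last label at {pos[-1]} kbp)"
            )
        if self.topology is Topology.LINEAR:
            if self.full_length_kbp is None:
                raise MissingFieldError("full_length_kbp: required for linear designs")
            if self.oric_term_offset_kbp >= self.full_length_kbp:
                raise GeometryError(
                    "oric_term_offset_kbp: must be smaller than full_length_kbp for linear designs"
                )
        else:
            if not self.cycle_starts_kbp:
                raise MissingFieldError("cycle_starts_kbp: required for circular designs")
            cs = self.cycle_starts_kbp
            if cs[0] != 0.0:
                raise GeometryError("cycle_starts_kbp: first cycle start must be 0")
            if any(b <= a for a, b in zip(cs, cs[1:])):
                raise GeometryError("cycle_starts_kbp: must be strictly increasing")

    # -- derived geometry ------------------------------------------------

    @property
    def n_cycles_max(self) -> int:
        return len(self.cycle_starts_kbp) if self.topology is Topology.CIRCULAR else 1

    def cycle_length_kbp(self, i: int) -> float:
        """Length of cycle ``i`` (0-based).

        For the last modelled cycle the previous increment is reused; a
        single-cycle design falls back to the OriC offset.
        """
        cs = self.cycle_starts_kbp
        if self.topology is Topology.LINEAR:
            return float(self.full_length_kbp)
        if i + 1 < len(cs):
            return cs[i + 1] - cs[i]
        if len(cs) >= 2:
            return cs[-1] - cs[-2]
        return self.oric_term_offset_kbp

    def oric_length_kbp(self, n: int) -> float:
        """Transcript length of an OriC-terminated product after ``n`` cycles."""
        if self.topology is Topology.LINEAR:
            return self.oric_term_offset_kbp
        return self.cycle_starts_kbp[n - 1] + self.oric_term_offset_kbp

    @property
    def max_length_kbp(self) -> float:
        """Longest transcript the design models."""
        if self.topology is Topology.LINEAR:
            return float(self.full_length_kbp)
        return self.cycle_starts_kbp[-1] + self.cycle_length_kbp(len(self.cycle_starts_kbp) - 1)


def _require(data: dict, key: str):
    if key not in data or data[key] is None:
        raise MissingFieldError(f"{key}: missing required field")
    return data[key]


def load_design(config_text: str) -> IDDesign:
    """Parse and validate an RNA ID design from YAML text.

    Labels may appear in any order in the config; they are sorted by
    position.  Raises a :class:`DesignError` subclass naming the offending
    field when validation fails.
    """
    data = yaml.safe_load(config_text)
    if not isinstance(data, dict):
        raise MissingFieldError("config: expected a mapping of design fields")
    topology = Topology(str(_require(data, "topology")))
    raw_labels = _require(data, "labels")
    labels = []
    for i, entry in enumerate(raw_labels):
        if not isinstance(entry, dict) or "position_kbp" not in entry:
            raise MissingFieldError(f"labels[{i}].position_kbp: missing required field")
        if "kind" not in entry:
            raise MissingFieldError(f"labels[{i}].kind: missing required field")
        try:
            kind = LabelKind(str(entry["kind"]))
        except ValueError as exc:
            raise GeometryError(f"labels[{i}].kind: unknown label kind {entry['kind']!r}") from exc
        labels.append(LabelSpec(float(entry["position_kbp"]), kind))
    labels.sort(key=lambda lab: lab.position_kbp)
    oric = float(_require(data, "oric_term_offset_kbp"))
    full_length = data.get("full_length_kbp")
    cycle_starts = data.get("cycle_starts_kbp") or ()
    if topology is Topology.LINEAR and full_length is None:
        raise MissingFieldError("full_length_kbp: required for linear designs")
    if topology is Topology.CIRCULAR and not cycle_starts:
        raise MissingFieldError("cycle_starts_kbp: required for circular designs")
    return IDDesign(
        topology=topology,
        labels=tuple(labels),
        oric_term_offset_kbp=oric,
        full_length_kbp=None if full_length is None else float(full_length),
        cycle_starts_kbp=tuple(cycle_starts),
    )


def load_design_file(path: str | Path) -> IDDesign:
    return load_design(Path(path).read_text())


def fixture_text(name: str) -> str:
    """Return the YAML text of a packaged design fixture (``linear`` / ``circular``)."""
    return resources.files("rnaid.data").joinpath(f"{name}_id.yaml").read_text()


def load_fixture(name: str) -> tuple[IDDesign, dict]:
    """Load a packaged fixture; returns the design plus simulator overrides.

    The fixture files carry, next to the geometry, the termination
    statistics of the construct (per-encounter OriC termination
    probability, dissociation hazard) under a ``sim`` key; those are
    returned as a plain dict to merge into simulation parameters.
    """
    data = yaml.safe_load(fixture_text(name))
    sim = data.pop("sim", None) or {}
    design = load_design(yaml.safe_dump(data))
    return design, dict(sim)


def layout_for_truth(
    design: IDDesign,
    true_length_kbp: float,
    orientation: str = "forward",
) -> list[tuple[float, LabelKind]]:
    """Labels present on a transcript of known length, in translocation order.

    Absolute label positions are ``cycle_start + within-cycle position`` for
    every modelled cycle that begins before ``true_length_kbp``.  ``reverse``
    orientation (3'->5' pore entry) returns mirrored positions
    ``true_length - p`` in ascending order, i.e. the order in which the pore
    sees the labels.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
    if true_length_kbp <= 0:
        raise GeometryError(f"true_length_kbp must be > 0, got {true_length_kbp}")
    if design.topology is Topology.CIRCULAR and true_length_kbp > design.max_length_kbp + 1e-9:
        raise GeometryError(
            f"true_length_kbp={true_length_kbp} exceeds the last modelled cycle end "
            f"({design.max_length_kbp} kbp)"
        )
    starts = design.cycle_starts_kbp if design.topology is Topology.CIRCULAR else (0.0,)
    out: list[tuple[float, LabelKind]] = []
    for start in starts:
        if start >= true_length_kbp:
            break
        for lab in design.labels:
            p = start + lab.position_kbp
            if p < true_length_kbp:
                out.append((p, lab.kind))
    if not out:
        warnings.warn(
            f"transcript of {true_length_kbp} kbp is shorter than the first label; no labels emitted",
            stacklevel=2,
        )
        return []
    if orientation == "reverse":
        out = sorted(((true_length_kbp - p, k) for p, k in out), key=lambda t: t[0])
    return out
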