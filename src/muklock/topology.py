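"""Catenation-parity model of the chromosome entrapment assay.

A covalently circularized protein compartment stays on chromosomal DNA
through denaturing electrophoresis only if it is catenated with the DNA.
For a closed DNA component passing through a compartment aperture, the
parity of transversal crossings decides catenation: an odd number of
crossings links the circles, an even number (including zero) lets the
protein slide off. A threading configuration lists, per closed DNA
component, how many times it crosses the ring and the clamp apertures;
the frame compartment (union of ring and clamp) is crossed by their sum.
Comparing predicted retention patterns against the observed one singles
out the threading topologies consistent with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from muklock.errors import DataError


@dataclass(frozen=True)
class DNAComponent:
    """A closed DNA with its crossing counts through ring and clamp."""

    component_id: str
    ring_crossings: int
    clamp_crossings: int

    def __post_init__(self) -> None:
        if self.ring_crossings < 0 or self.clamp_crossings < 0:
            raise DataError("crossing counts must be >= 0")

    @property
    def frame_crossings(self) -> int:
        return self.ring_crossings + self.clamp_crossings


@dataclass(frozen=True)
class ThreadingConfig:
    name: str
    components: tuple  # of DNAComponent
    note: str = ""


@dataclass(frozen=True)
class RetentionPattern:
    ring: bool
    clamp: bool
    frame: bool


def is_catenated(crossings: int) -> bool:
    """True iff a closed curve with this many transversal crossings of a
    spanning disk is catenated with the circle (odd parity)."""
    if crossings < 0:
        raise DataError("crossings must be >= 0")
    return crossings % 2 == 1


def predict_retention(config: ThreadingConfig) -> RetentionPattern:
    """Predicted retention of each circularized compartment.

    A compartment retains DNA iff at least one DNA component is catenated
    with it; the frame sees the per-component sum of ring and clamp
    crossings.
    """
    return RetentionPattern(
        ring=any(is_catenated(c.ring_crossings) for c in config.components),
        clamp=any(is_catenated(c.clamp_crossings) for c in config.components),
        frame=any(is_catenated(c.frame_crossings) for c in config.components),
    )


def consistent_configs(
    observed: RetentionPattern,
    candidates: Sequence[ThreadingConfig],
) -> list[ThreadingConfig]:
    """Candidates whose predicted retention equals the observed pattern."""
    if len(candidates) == 0:
        raise DataError("at least one candidate configuration is required")
    return [c for c in candidates if predict_retention(c) == observed]


def default_candidates() -> list[ThreadingConfig]:
    """The shipped candidate threading topologies.

    double_lock: the two arms of one loop pass separately through ring and
    clamp. ring_only/clamp_only: a single passage through one compartment.
    sisters: two distinct chromosomes, one through each compartment.
    parallel_axis_loop: a loop whose axis lies in the ring plane so the
    loop tip is enclosed by the ring; like ring_only it crosses the ring
    aperture once per closed chromosome and is therefore catenated with
    the frame, contradicting the frame's observed non-retention.
    pseudo_topological: a loop poked through and back (two crossings).
    non_topological: DNA merely bound at the surface.
    """
    c = DNAComponent
    return [
        ThreadingConfig("double_lock", (c("loop", 1, 1),),
                        "one loop, one arm in the ring and one in the clamp"),
        ThreadingConfig("ring_only", (c("dna", 1, 0),),
                        "single passage through the ring"),
        ThreadingConfig("clamp_only", (c("dna", 0, 1),),
                        "single passage through the clamp"),
        ThreadingConfig("sisters",
                        (c("sister_1", 1, 0), c("sister_2", 0, 1)),
                        "sister chromosomes entrapped separately"),
        ThreadingConfig("parallel_axis_loop", (c("loop", 1, 0),),
                        "loop axis parallel to the ring plane; the enclosed "
                        "loop tip still crosses the ring aperture once, a "
                        "modelling choice for a schematic geometry"),
        ThreadingConfig("pseudo_topological", (c("loop", 2, 0),),
                        "loop threaded in and back out of the ring"),
        ThreadingConfig("non_topological", (c("dna", 0, 0),),
                        "surface-bound DNA, no threading"),
    ]
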