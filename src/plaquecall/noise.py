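"""Background-error ("false mutation proportion") estimation and subtraction.

PCR and semiconductor-sequencing artefacts produce a reproducible, position-
and event-specific background: the same wrong base or indel shows up at a
similar read fraction in every pooled library.  The false mutation
proportion for each (position, event) is therefore estimated as the *median*
of that event's read proportion across all libraries -- robust to the
occasional library that carries the event as a real mutation -- and
subtracted from each library's total proportion to leave the true mutation
proportion, floored at zero.

Indels at homopolymers can have background far above anything seen for
substitutions; indel events whose false proportion exceeds the highest
substitution false proportion (the *indel cap*) are masked out of calling
entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pileup_counts import EventKey, ProportionMatrix, is_indel


class AlignmentError(ValueError):
    """Libraries do not share a common position range."""


@dataclass
class NoiseProfile:
    """Cross-library median background per event, plus the indel cap."""

    false_prop: dict
    n_libraries: int
    length: int
    indel_cap: float = field(init=False)

    def __post_init__(self) -> None:
        subs = [p for e, p in self.false_prop.items() if e.kind == "sub"]
        self.indel_cap = max(subs) if subs else 0.0

    def get(self, event: EventKey) -> float:
        return self.false_prop.get(event, 0.0)


def estimate_noise(proportion_matrices: list[ProportionMatrix], exclude: str | None = None) -> NoiseProfile:
    """Median event proportion across libraries for every observed event.

    Events absent from a library contribute proportion 0 there, so the
    median is over the full library panel.  ``exclude`` drops one library id
    first (leave-one-out mode).  Requires at least three libraries.
    """
    if exclude is not None:
        proportion_matrices = [m for m in proportion_matrices if m.library_id != exclude]
    n = len(proportion_matrices)
    if n < 3:
        raise ValueError(f"need >=3 libraries for a meaningful median, got {n}")
    lengths = {m.length for m in proportion_matrices}
    if len(lengths) != 1:
        raise AlignmentError(f"libraries span different position ranges: {sorted(lengths)}")
    events = set()
    for m in proportion_matrices:
        events.update(m.props)
    false_prop = {}
    for event in events:
        values = np.zeros(n)
        for i, m in enumerate(proportion_matrices):
            values[i] = m.props.get(event, 0.0)
        med = float(np.median(values))
        if med > 0.0:
            false_prop[event] = med
    return NoiseProfile(false_prop=false_prop, n_libraries=n, length=lengths.pop())


def subtract_noise(proportions: ProportionMatrix, profile: NoiseProfile) -> ProportionMatrix:
    """True proportion = max(0, total - false), elementwise."""
    if proportions.length != profile.length:
        raise AlignmentError(
            f"library length {proportions.length} does not match profile length {profile.length}"
        )
    true_props = {}
    for event, total in proportions.props.items():
        value = total - profile.get(event)
        if value > 0.0:
            true_props[event] = value
    return ProportionMatrix(
        library_id=proportions.library_id,
        length=proportions.length,
        depth=proportions.depth,
        props=true_props,
    )


def indel_mask(profile: NoiseProfile) -> set[EventKey]:
    """Indel events with background strictly above the substitution cap."""
    return {
        event
        for event, prop in profile.false_prop.items()
        if is_indel(event) and prop > profile.indel_cap
    }


def write_noise_tsv(profile: NoiseProfile, path, mask: set | None = None) -> None:
    """Serialize the profile (and optionally the mask flag) for audit."""
    mask = mask or set()
    with open(path, "w") as handle:
        handle.write(
            f"# plaquecall-noise v1\tn_libraries={profile.n_libraries}"
            f"\tlength={profile.length}\tindel_cap={profile.indel_cap!r}\n"
        )
        handle.write("position\tkind\tdetail\tfalse_prop\tmasked\n")
        for event in sorted(profile.false_prop, key=lambda e: (e.position, e.kind, str(e.detail))):
            handle.write(
                f"{event.position}\t{event.kind}\t{event.detail}\t"
                f"{profile.false_prop[event]!r}\t{int(event in mask)}\n"
            )


def read_noise_tsv(path) -> NoiseProfile:
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if not header.startswith("# plaquecall-noise v1"):
            raise ValueError(f"{path}: missing noise-TSV magic header")
        meta = dict(item.split("=", 1) for item in header.split("\t")[1:])
        handle.readline()  # column header
        false_prop = {}
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            pos_s, kind, detail, prop_s, _masked = line.split("\t")
            event = EventKey(int(pos_s), kind, int(detail) if kind == "del" else detail)
            false_prop[event] = float(prop_s)
    return NoiseProfile(
        false_prop=false_prop, n_libraries=int(meta["n_libraries"]), length=int(meta["length"])
    )
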