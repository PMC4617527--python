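"""Threshold-based mutation calling from technical-replicate pairs.

A pool of n mutant plaques is sequenced as one library, so one mutant plaque
contributes ~1/n of the reads at its mutated position.  A mutation is called
when its noise-subtracted (true) proportion reaches the plaque-count-derived
threshold in BOTH PCR replicates -- replicate concordance is the filter that
removes single-replicate PCR jackpots.  The average replicate proportion
divided by the expected single-plaque proportion gives a rough copy count,
later calibrated by the clonality model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .noise import AlignmentError
from .pileup_counts import EventKey, ProportionMatrix, is_indel
from .reference import ProteinImpact, ReferenceGene, classify_impact

STRINGENCIES = (1.0, 0.75, 0.5)


@dataclass
class SamplePool:
    """One animal's pooled mutant plaques with its phage titres."""

    animal_id: str
    group: str  # "control" | "treated"
    n_plaques: int
    mutant_pfu: int
    total_pfu: int
    replicate_ids: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_plaques < 1:
            raise ValueError("n_plaques must be >= 1")
        if self.mutant_pfu > self.total_pfu:
            raise ValueError("mutant_pfu cannot exceed total_pfu")
        if len(self.replicate_ids) != 2:
            raise ValueError("exactly two technical replicates required")

    @property
    def mutant_frequency(self) -> float:
        if self.total_pfu <= 0:
            raise ValueError("total_pfu must be positive")
        return self.mutant_pfu / self.total_pfu


@dataclass
class MutationCall:
    event: EventKey
    true_prop_rep1: float
    true_prop_rep2: float
    threshold_used: float
    raw_count: int
    adjusted_count: int
    sample: str = ""
    impact: ProteinImpact | None = None

    @property
    def mean_true_prop(self) -> float:
        return (self.true_prop_rep1 + self.true_prop_rep2) / 2.0


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def calling_threshold(n_plaques: int, stringency: float = 1.0) -> float:
    """stringency x (1 / n_plaques): the read proportion one plaque should reach."""
    if n_plaques < 1:
        raise ValueError("n_plaques must be >= 1")
    if not 0.0 < stringency <= 1.0:
        raise ValueError("stringency must be in (0, 1]")
    return stringency * (1.0 / n_plaques)


def call_mutations(
    rep1_true: ProportionMatrix,
    rep2_true: ProportionMatrix,
    n_plaques: int,
    stringency: float = 1.0,
    indel_mask: set | None = None,
    gene: ReferenceGene | None = None,
    sample: str = "",
) -> list[MutationCall]:
    """Call events reaching the threshold in both replicates.

    The copy estimate always divides by the stringency-1.0 expected
    proportion (1/n_plaques) so that counts mean "plaques among the pool"
    regardless of the calling stringency; round half up, floor 1.  Indels in
    the background mask are never called; impacts are classified when the
    event lies in the coding region of ``gene``.
    """
    if rep1_true.length != rep2_true.length:
        raise AlignmentError("replicate position ranges differ")
    indel_mask = indel_mask or set()
    threshold = calling_threshold(n_plaques, stringency)
    expected_single = calling_threshold(n_plaques, 1.0)
    calls: list[MutationCall] = []
    for event in sorted(
        set(rep1_true.props) | set(rep2_true.props),
        key=lambda e: (e.position, e.kind, str(e.detail)),
    ):
        p1 = rep1_true.get(event)
        p2 = rep2_true.get(event)
        if min(p1, p2) < threshold:
            continue
        if is_indel(event) and event in indel_mask:
            continue
        raw = max(1, round_half_up(((p1 + p2) / 2.0) / expected_single))
        impact = None
        if gene is not None and gene.in_coding_region(event.position):
            impact = classify_impact(gene, event.position, event)
        calls.append(
            MutationCall(
                event=event,
                true_prop_rep1=p1,
                true_prop_rep2=p2,
                threshold_used=threshold,
                raw_count=raw,
                adjusted_count=raw,
                sample=sample,
                impact=impact,
            )
        )
    return calls


def concordance_failures(
    rep1_true: ProportionMatrix, rep2_true: ProportionMatrix, n_plaques: int, stringency: float = 1.0
) -> list[EventKey]:
    """Events above threshold in exactly one replicate ("mutants removed")."""
    threshold = calling_threshold(n_plaques, stringency)
    events = set(rep1_true.props) | set(rep2_true.props)
    return sorted(
        (
            e
            for e in events
            if (rep1_true.get(e) >= threshold) != (rep2_true.get(e) >= threshold)
        ),
        key=lambda e: (e.position, e.kind, str(e.detail)),
    )


def tabulate_mutations(calls: Iterable[MutationCall], use_adjusted: bool = False) -> dict:
    """Per-call-set summary: independent (distinct events), total, recurrent."""
    calls = list(calls)
    independent = len({c.event for c in calls})
    total = sum((c.adjusted_count if use_adjusted else c.raw_count) for c in calls)
    return {"independent": independent, "total": total, "recurrent": total - independent}


def read_sample_sheet(path) -> list[SamplePool]:
    """Sample sheet TSV: animal_id, group, n_plaques, mutant_pfu, total_pfu[, rep1, rep2]."""
    pools: list[SamplePool] = []
    with open(path) as handle:
        header = None
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0] == "animal_id":
                header = fields
                continue
            reps = tuple(fields[5:7]) if len(fields) >= 7 else ("A", "B")
            pools.append(
                SamplePool(
                    animal_id=fields[0],
                    group=fields[1],
                    n_plaques=int(fields[2]),
                    mutant_pfu=int(fields[3]),
                    total_pfu=int(fields[4]),
                    replicate_ids=reps,
                )
            )
    return pools


def write_sample_sheet(pools: Iterable[SamplePool], path) -> None:
    with open(path, "w") as handle:
        handle.write("animal_id\tgroup\tn_plaques\tmutant_pfu\ttotal_pfu\trep1\trep2\n")
        for p in pools:
            handle.write(
                f"{p.animal_id}\t{p.group}\t{p.n_plaques}\t{p.mutant_pfu}\t{p.total_pfu}"
                f"\t{p.replicate_ids[0]}\t{p.replicate_ids[1]}\n"
            )


def read_calls_tsv(path) -> list[MutationCall]:
    """Read back a calls TSV written by :func:`write_calls_tsv`."""
    calls: list[MutationCall] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            kind = fields[idx["kind"]]
            pos = int(fields[idx["pos"]])
            ref, alt = fields[idx["ref"]], fields[idx["alt"]]
            if kind == "sub":
                detail: object = alt
            elif kind == "ins":
                detail = alt[1:]
            else:
                detail = len(ref)
            impact_s = fields[idx["impact"]]
            calls.append(
                MutationCall(
                    event=EventKey(pos, kind, detail),
                    true_prop_rep1=float(fields[idx["true_prop_rep1"]]),
                    true_prop_rep2=float(fields[idx["true_prop_rep2"]]),
                    threshold_used=float(fields[idx["threshold"]]),
                    raw_count=int(fields[idx["raw_count"]]),
                    adjusted_count=int(fields[idx["adjusted_count"]]),
                    sample=fields[idx["sample"]],
                    impact=None if impact_s == "." else ProteinImpact(impact_s),
                )
            )
    return calls


def write_calls_tsv(calls: Iterable[MutationCall], gene: ReferenceGene, path) -> None:
    """VCF-like tidy TSV of calls (CHROM, 1-based POS, REF, ALT, metrics)."""
    with open(path, "w") as handle:
        handle.write(
            "chrom\tpos\tref\talt\tkind\tsample\ttrue_prop_rep1\ttrue_prop_rep2"
            "\tthreshold\traw_count\tadjusted_count\timpact\n"
        )
        for c in sorted(calls, key=lambda c: (c.sample, c.event.position, c.event.kind, str(c.event.detail))):
            pos = c.event.position
            if c.event.kind == "sub":
                ref, alt = gene.base(pos), str(c.event.detail)
            elif c.event.kind == "ins":
                ref = gene.base(pos) if pos >= 1 else "."
                alt = ref + str(c.event.detail)
            else:
                ref = gene.sequence[pos - 1 : pos - 1 + int(c.event.detail)]
                alt = "."
            impact = c.impact.value if c.impact is not None else "."
            handle.write(
                f"{gene.name}\t{pos}\t{ref}\t{alt}\t{c.event.kind}\t{c.sample}"
                f"\t{c.true_prop_rep1!r}\t{c.true_prop_rep2!r}\t{c.threshold_used!r}"
                f"\t{c.raw_count}\t{c.adjusted_count}\t{impact}\n"
            )
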