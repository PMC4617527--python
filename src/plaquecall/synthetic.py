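"""Synthetic pooled-plaque sequencing data with known truth.

Emulates the pooled-plaque assay end to end: each animal contributes a pool
of n mutant plaques, each plaque carrying one phenotype-driving mutation;
clonal expansion makes some plaques copies of earlier ones; the pool is
PCR-amplified twice (technical replicates) and sequenced deep, so a mutation
carried by k plaques appears in ~k/n of the reads.  On top of the signal sit
three error layers: a positional noise field (per-position, per-event rates
shared across ALL libraries, log-uniform over the observed substitution
background range), indel noise elevated at homopolymer runs, and
replicate-specific PCR "jackpot" errors (an early-cycle polymerase error
propagates to a 2^-c read fraction in that replicate only).

Every stage of the calling pipeline is testable against the returned truth
table without any sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calling import SamplePool, round_half_up
from .noise import NoiseProfile
from .pileup_counts import (
    EventKey,
    PositionCountMatrix,
    left_align_deletion,
    left_align_insertion,
)
from .reference import ReferenceGene
from .spectrum_stats import ALL_CLASSES, DELETION, INSERTION, SUB_CLASSES

#: BaP-like per-class probabilities.  Aggregates: transitions 0.14,
#: transversions 0.61, indels 0.25, dominated by guanine transversions.
DEFAULT_CLASS_PROBS = {
    "GC>AT": 0.10,
    "AT>GC": 0.04,
    "GC>TA": 0.38,
    "GC>CG": 0.15,
    "AT>TA": 0.05,
    "AT>CG": 0.03,
    INSERTION: 0.05,
    DELETION: 0.20,
}

#: spontaneous-background-like alternative (transitions 0.35,
#: transversions 0.49, indels 0.16)
CONTROL_CLASS_PROBS = {
    "GC>AT": 0.25,
    "AT>GC": 0.10,
    "GC>TA": 0.22,
    "GC>CG": 0.12,
    "AT>TA": 0.09,
    "AT>CG": 0.06,
    INSERTION: 0.04,
    DELETION: 0.12,
}


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the generator; defaults mirror the assay design."""

    gene: ReferenceGene
    n_samples: int = 6  # per group
    n_plaques: int = 300
    clonal_fraction: float = 0.3
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    hotspot_weights: np.ndarray | None = None
    depth: int = 50_000
    sub_noise_range: tuple[float, float] = (1.7e-5, 2.15e-2)
    indel_noise_multiplier_at_homopolymers: float = 10.0
    homopolymer_min_len: int = 3
    pcr_error_rate: float = 1e-3  # per-base per-replicate jackpot probability
    hitchhiker_rate: float = 0.0
    groups: tuple[str, ...] = ("control", "treated")
    mutant_frequency: dict = field(
        default_factory=lambda: {"control": 8.6e-5, "treated": 701.7e-5}
    )
    total_pfu: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_probs sum to {total}, expected 1")
        unknown = set(self.class_probs) - set(ALL_CLASSES)
        if unknown:
            raise ConfigError(f"unknown mutation classes {sorted(unknown)}")
        if not 0.0 <= self.clonal_fraction < 1.0:
            raise ConfigError("clonal_fraction must be in [0, 1)")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.n_plaques < 1:
            raise ConfigError("n_plaques must be >= 1")
        lo, hi = self.sub_noise_range
        if lo < 0 or hi < lo:
            raise ConfigError("invalid sub_noise_range")
        if self.hotspot_weights is not None:
            w = np.asarray(self.hotspot_weights, dtype=float)
            if w.shape != (len(self.gene),) or (w < 0).any() or w.sum() <= 0:
                raise ConfigError("hotspot_weights must be a non-negative length-L vector")
            self.hotspot_weights = w


@dataclass(frozen=True)
class TrueMutation:
    event: EventKey
    copies: int
    mutation_class: str
    driving: bool = True


@dataclass
class TruthTable:
    """Generating truth: mutations per animal and the shared noise field."""

    mutations: dict  # animal_id -> list[TrueMutation]
    n_plaques: dict  # animal_id -> int

    def driving_copies(self, animal_id: str) -> int:
        return sum(m.copies for m in self.mutations[animal_id] if m.driving)

    def events(self, animal_id: str) -> set[EventKey]:
        return {m.event for m in self.mutations[animal_id]}


@dataclass
class SimResult:
    pools: list[SamplePool]
    matrices: dict  # animal_id -> (PositionCountMatrix, PositionCountMatrix)
    truth: TruthTable
    noise_truth: NoiseProfile
    config: SimConfig


def random_gene(length: int = 600, seed: int = 0, name: str = "toy_gene") -> ReferenceGene:
    """A random toy reporter gene (complete coding frame) for fast tests."""
    length -= length % 3
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return ReferenceGene(name=name, sequence=seq)


# --- noise field ----------------------------------------------------------

def _canonical_ins(sequence: str, anchor: int, inserted: str) -> EventKey:
    a, s = left_align_insertion(sequence, anchor, inserted)
    return EventKey(max(a, 1), "ins", s)


def _canonical_del(sequence: str, start: int, length: int) -> EventKey:
    return EventKey(left_align_deletion(sequence, start, length), "del", length)


def _base_runs(sequence: str) -> list[tuple[int, int, str]]:
    """All maximal same-base runs (any length >= 1) as (start, length, base)."""
    runs = []
    i, n = 0, len(sequence)
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        runs.append((i + 1, j - i, sequence[i]))
        i = j
    return runs


def build_noise_field(config: SimConfig, rng: np.random.Generator) -> dict:
    """Per-event background rates shared across all libraries.

    Substitutions: one log-uniform rate per (position, alternate base).
    Indels: one 1-bp slippage insertion and one 1-bp deletion per same-base
    run (left-aligned canonical keys), elevated by the homopolymer
    multiplier at runs of length >= the configured minimum.
    """
    seq = config.gene.sequence
    lo, hi = config.sub_noise_range

    def draw(size):
        if lo == hi == 0.0:
            return np.zeros(size)
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    rates: dict[EventKey, float] = {}
    bases = "ACGT"
    for p, ref in enumerate(seq, start=1):
        for alt in bases:
            if alt != ref:
                rates[EventKey(p, "sub", alt)] = float(draw(1)[0])
    for start, length, base in _base_runs(seq):
        mult = (
            config.indel_noise_multiplier_at_homopolymers
            if length >= config.homopolymer_min_len
            else 1.0
        )
        ins_key = _canonical_ins(seq, start + length - 1, base)
        del_key = _canonical_del(seq, start, 1)
        rates[ins_key] = float(min(draw(1)[0] * mult, 0.95))
        rates[del_key] = float(min(draw(1)[0] * mult, 0.95))
    return rates


# --- true mutations -------------------------------------------------------

def _position_weights(config: SimConfig) -> np.ndarray:
    if config.hotspot_weights is not None:
        return np.asarray(config.hotspot_weights, dtype=float)
    return np.ones(len(config.gene))


def _draw_event(config: SimConfig, rng: np.random.Generator, mclass: str) -> EventKey:
    seq = config.gene.sequence
    weights = _position_weights(config)
    if mclass in SUB_CLASSES:
        pair, target = mclass.split(">")  # e.g. "GC", "TA"
        eligible = np.array([i for i, b in enumerate(seq) if b in pair])
        w = weights[eligible]
        idx = int(rng.choice(eligible, p=w / w.sum()))
        ref = seq[idx]
        # purine-strand base maps to target[0], pyrimidine to target[1]
        alt = target[0] if ref == pair[0] else target[1]
        return EventKey(idx + 1, "sub", alt)
    w = weights / weights.sum()
    idx = int(rng.choice(len(seq), p=w))
    if mclass == INSERTION:
        return _canonical_ins(seq, idx + 1, seq[idx])
    if mclass == DELETION:
        return _canonical_del(seq, idx + 1, 1)
    raise ConfigError(f"unknown mutation class {mclass!r}")


def _silent_candidates(config: SimConfig, rng: np.random.Generator) -> EventKey:
    """A random silent substitution (hitchhiker); falls back to any sub."""
    from .reference import ProteinImpact, classify_impact

    gene = config.gene
    for _ in range(200):
        p = int(rng.integers(1, len(gene) + 1))
        ref = gene.base(p)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        event = EventKey(p, "sub", alt)
        if gene.in_coding_region(p) and classify_impact(gene, p, event) is ProteinImpact.SILENT:
            return event
    return event  # pragma: no cover - practically unreachable


def draw_sample_truth(
    config: SimConfig, rng: np.random.Generator, class_probs: dict
) -> list[TrueMutation]:
    """Assign one driving mutation per plaque, with clonal duplication.

    Each plaque either duplicates the mutation of a uniformly chosen earlier
    plaque (probability ``clonal_fraction``) or draws a fresh mutation by
    class and hotspot-weighted position.  Fresh draws are redrawn on
    collision with an existing event (up to a cap), so recurrent copies in
    the truth arise from clonal duplication only and a run with
    ``clonal_fraction`` 0 yields all-distinct single-copy events.
    """
    classes = list(class_probs)
    probs = np.array([class_probs[c] for c in classes])
    probs = probs / probs.sum()
    by_event: dict[EventKey, list] = {}
    plaque_events: list[EventKey] = []
    for _ in range(config.n_plaques):
        if plaque_events and rng.random() < config.clonal_fraction:
            event = plaque_events[int(rng.integers(len(plaque_events)))]
            by_event[event][1] += 1
        else:
            for _attempt in range(100):
                mclass = classes[int(rng.choice(len(classes), p=probs))]
                event = _draw_event(config, rng, mclass)
                if event not in by_event:
                    break
            if event in by_event:
                by_event[event][1] += 1
            else:
                by_event[event] = [mclass, 1, True]
        plaque_events.append(event)
        if config.hitchhiker_rate > 0 and rng.random() < config.hitchhiker_rate:
            from .spectrum_stats import classify

            extra = _silent_candidates(config, rng)
            if extra in by_event:
                by_event[extra][1] += 1
            else:
                cls = classify(config.gene.base(extra.position), extra)
                by_event[extra] = [cls, 1, False]
    return [
        TrueMutation(event=e, copies=c, mutation_class=m, driving=d)
        for e, (m, c, d) in by_event.items()
    ]


# --- read-count generation ------------------------------------------------

def _sample_library(
    config: SimConfig,
    rng: np.random.Generator,
    library_id: str,
    noise_rates: dict,
    truth: Sequence[TrueMutation],
) -> PositionCountMatrix:
    """Draw one replicate's counts: multinomial per position over its events.

    Per-position multinomial sampling guarantees the event counts at a
    position never exceed its depth.
    """
    L = len(config.gene)
    per_position: dict[int, dict[EventKey, float]] = {}

    def add_rate(event: EventKey, rate: float) -> None:
        per_position.setdefault(event.position, {})
        per_position[event.position][event] = per_position[event.position].get(event, 0.0) + rate

    for event, rate in noise_rates.items():
        if rate > 0:
            add_rate(event, rate)
    for mutation in truth:
        add_rate(mutation.event, mutation.copies / config.n_plaques)

    # replicate-specific PCR jackpots: an error in cycle c reaches 2^-c of reads
    n_jackpots = rng.binomial(L, config.pcr_error_rate)
    for _ in range(n_jackpots):
        p = int(rng.integers(1, L + 1))
        ref = config.gene.base(p)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        cycle = int(rng.integers(3, 12))
        add_rate(EventKey(p, "sub", alt), 2.0**-cycle)

    positions = sorted(per_position)
    max_k = max((len(per_position[p]) for p in positions), default=0)
    probs = np.zeros((len(positions), max_k + 1))
    keys: list[list[EventKey]] = []
    for i, p in enumerate(positions):
        events = sorted(per_position[p].items(), key=lambda kv: (kv[0].kind, str(kv[0].detail)))
        keys.append([e for e, _ in events])
        row = np.array([r for _, r in events])
        total = row.sum()
        if total > 1.0:
            row = row / total
            total = 1.0
        probs[i, : len(row)] = row
        probs[i, max_k] = max(0.0, 1.0 - row.sum())
    # remainder (reference reads) sits in the last column; padding columns
    # beyond each row's event count carry probability 0
    matrix = PositionCountMatrix(library_id=library_id, length=L)
    matrix.depth[:] = config.depth
    if positions:
        draws = rng.multinomial(config.depth, probs)
        for i, p in enumerate(positions):
            for j, event in enumerate(keys[i]):
                count = int(draws[i, j])
                if count > 0:
                    matrix.add(event, count)
    return matrix


def simulate_pools(config: SimConfig, class_probs_by_group: dict | None = None) -> SimResult:
    """Generate every library of a two-group study plus its truth.

    Returns paired replicate count matrices per animal, the per-animal truth
    table, and the generating noise field as a NoiseProfile.  With the seed
    fixed the output is bit-identical across runs.
    """
    rng = np.random.default_rng(config.seed)
    noise_rates = build_noise_field(config, rng)
    pools: list[SamplePool] = []
    matrices: dict[str, tuple[PositionCountMatrix, PositionCountMatrix]] = {}
    mutations: dict[str, list[TrueMutation]] = {}
    n_plaques: dict[str, int] = {}
    for group in config.groups:
        probs = (class_probs_by_group or {}).get(group, config.class_probs)
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_probs for group {group} sum to {total}")
        mf = config.mutant_frequency.get(group, 1e-4)
        for i in range(config.n_samples):
            animal = f"{group}{i + 1}"
            truth = draw_sample_truth(config, rng, probs)
            mutations[animal] = truth
            n_plaques[animal] = config.n_plaques
            rep_a = _sample_library(config, rng, f"{animal}.A", noise_rates, truth)
            rep_b = _sample_library(config, rng, f"{animal}.B", noise_rates, truth)
            matrices[animal] = (rep_a, rep_b)
            mutant_pfu = int(rng.poisson(mf * config.total_pfu))
            pools.append(
                SamplePool(
                    animal_id=animal,
                    group=group,
                    n_plaques=config.n_plaques,
                    mutant_pfu=min(mutant_pfu, config.total_pfu),
                    total_pfu=config.total_pfu,
                    replicate_ids=(f"{animal}.A", f"{animal}.B"),
                )
            )
    noise_truth = NoiseProfile(
        false_prop=dict(noise_rates), n_libraries=0, length=len(config.gene)
    )
    return SimResult(
        pools=pools,
        matrices=matrices,
        truth=TruthTable(mutations=mutations, n_plaques=n_plaques),
        noise_truth=noise_truth,
        config=config,
    )


def simulate_wildtype_pools(config: SimConfig, n_pools: int = 6) -> SimResult:
    """Noise-only negative controls: wild-type plaques carry no mutations."""
    rng = np.random.default_rng(config.seed)
    noise_rates = build_noise_field(config, rng)
    pools, matrices, mutations, n_plaques = [], {}, {}, {}
    for i in range(n_pools):
        animal = f"wildtype{i + 1}"
        mutations[animal] = []
        n_plaques[animal] = config.n_plaques
        rep_a = _sample_library(config, rng, f"{animal}.A", noise_rates, [])
        rep_b = _sample_library(config, rng, f"{animal}.B", noise_rates, [])
        matrices[animal] = (rep_a, rep_b)
        pools.append(
            SamplePool(
                animal_id=animal,
                group="control",
                n_plaques=config.n_plaques,
                mutant_pfu=0,
                total_pfu=config.total_pfu,
                replicate_ids=(f"{animal}.A", f"{animal}.B"),
            )
        )
    noise_truth = NoiseProfile(false_prop=dict(noise_rates), n_libraries=0, length=len(config.gene))
    return SimResult(
        pools=pools,
        matrices=matrices,
        truth=TruthTable(mutations=mutations, n_plaques=n_plaques),
        noise_truth=noise_truth,
        config=config,
    )


# --- calibration mixtures -------------------------------------------------

def simulate_calibration_mixture(
    copies_list: Sequence[int],
    gene: ReferenceGene,
    depth: int = 50_000,
    noise: dict | None = None,
    seed: int = 0,
    plaque_weights: Sequence[float] | None = None,
):
    """Constructed mixture of known copy numbers, like the assay's control libraries.

    Distinct substitutions are planted with the given copy numbers (optionally
    weighted by per-plaque read-weight multipliers emulating plaque size);
    two replicates are drawn and a rough observed count is computed for each
    mutation by dividing its mean proportion by the single-copy expectation.
    With ``noise=None`` the counts are deterministic (expected values).

    Returns (calibration_points, (rep_a, rep_b), truth_events).
    """
    from .clonality import CalibrationPoint

    copies = [int(c) for c in copies_list]
    if any(c < 1 for c in copies):
        raise ValueError("copy numbers must be >= 1")
    n = sum(copies)
    weights = list(plaque_weights) if plaque_weights is not None else [1.0] * len(copies)
    if len(weights) != len(copies):
        raise ValueError("plaque_weights must match copies_list")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(gene), size=len(copies), replace=False) + 1
    events = []
    mass = sum(c * w for c, w in zip(copies, weights))
    for p, c, w in zip(positions, copies, weights):
        ref = gene.base(int(p))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        events.append((EventKey(int(p), "sub", alt), c, (c * w) / mass))

    def one_replicate(library_id: str) -> PositionCountMatrix:
        matrix = PositionCountMatrix(library_id=library_id, length=len(gene))
        matrix.depth[:] = depth
        for event, _, prop in events:
            rate = prop + (noise.get(event, 0.0) if noise else 0.0)
            count = rng.binomial(depth, min(rate, 1.0)) if noise else round_half_up(depth * rate)
            if count > 0:
                matrix.add(event, count)
        if noise:
            for event, rate in noise.items():
                if rate > 0 and all(event != e for e, _, _ in events):
                    count = rng.binomial(depth, min(rate, 1.0))
                    if count > 0:
                        matrix.add(event, count)
        return matrix

    rep_a = one_replicate("calibration.A")
    rep_b = one_replicate("calibration.B")
    points = []
    for event, c, _ in events:
        p1 = rep_a.counts.get(event, 0) / depth
        p2 = rep_b.counts.get(event, 0) / depth
        observed = max(0, round_half_up(((p1 + p2) / 2.0) * n))
        points.append(CalibrationPoint(expected_count=c, observed_count=observed))
    return points, (rep_a, rep_b), [e for e, _, _ in events]


# --- pileup emission (small depths; for parser oracle tests) --------------

def emit_pileup(matrix: PositionCountMatrix, gene: ReferenceGene, path) -> None:
    """Write samtools-pileup text reproducing the matrix's event counts.

    Deletion events at position s are rendered as ``.-<len><seq>`` on line
    s-1 with ``*`` placeholders on the deleted lines, insertions as
    ``.+<len><seq>`` at their anchor; both therefore re-parse to the same
    left-aligned keys.  Intended for small test matrices (the read column
    grows linearly with depth).
    """
    seq = gene.sequence
    L = matrix.length
    attach: dict[int, list[str]] = {}
    stars: dict[int, int] = {}
    plain: dict[int, list[str]] = {}
    for event, count in sorted(matrix.counts.items()):
        p, kind, detail = event
        if kind == "sub":
            plain.setdefault(p, []).extend([str(detail)] * count)
        elif kind == "ins":
            attach.setdefault(p, []).extend([f"+{len(str(detail))}{detail}"] * count)
        elif kind == "del":
            length = int(detail)
            if p < 2:
                raise ValueError("cannot render a deletion starting at position 1 in pileup text")
            deleted = seq[p - 1 : p - 1 + length]
            attach.setdefault(p - 1, []).extend([f"-{length}{deleted}"] * count)
            for q in range(p, p + length):
                stars[q] = stars.get(q, 0) + count
    with open(path, "w") as handle:
        for p in range(1, L + 1):
            depth = int(matrix.depth[p - 1])
            tokens = list(plain.get(p, []))
            tokens += ["." + suffix for suffix in attach.get(p, [])]
            tokens += ["*"] * stars.get(p, 0)
            n_ref = depth - len(tokens)
            if n_ref < 0:
                raise ValueError(f"position {p}: events exceed depth, cannot render")
            tokens += ["."] * n_ref
            handle.write(f"{gene.name}\t{p}\t{seq[p - 1]}\t{depth}\t{''.join(tokens)}\tI\n")
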