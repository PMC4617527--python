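"""Mutation spectra, group statistics, hotspots and power simulation.

Substitutions are collapsed over complementary strands into the six classes
standard in mutation-reporter work (G:C→A:T, G:C→T:A, G:C→C:G, A:T→G:C,
A:T→T:A, A:T→C:G), written here as ``GC>AT`` etc.; insertions and deletions
are classes of their own.  Spectra are built from independent mutations
(distinct events per animal) unless recurrent copies are explicitly
requested.  Groups are compared with Pearson's chi-squared test of
independence (Monte-Carlo p when expected cells are small) and with Poisson
regression of mutant plaque counts offset by total pfu.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .calling import MutationCall, SamplePool
from .pileup_counts import EventKey
from .reference import COMPLEMENT, HomopolymerRun, ReferenceGene

SUB_CLASSES = ("GC>AT", "GC>TA", "GC>CG", "AT>GC", "AT>TA", "AT>CG")
INSERTION = "ins"
DELETION = "del"
ALL_CLASSES = SUB_CLASSES + (INSERTION, DELETION)
TRANSITIONS = frozenset({"GC>AT", "AT>GC"})

#: default draw count and seed for Monte-Carlo p-values
MC_DRAWS = 100_000
MC_SEED = 20151019


def classify(ref_base: str, event: EventKey) -> str:
    """Complement-collapsed mutation class of an event at a reference base."""
    if event.kind == "ins":
        return INSERTION
    if event.kind == "del":
        return DELETION
    ref = ref_base.upper()
    alt = str(event.detail).upper()
    if ref not in COMPLEMENT or alt not in COMPLEMENT:
        raise ValueError(f"invalid bases {ref_base!r} -> {event.detail!r}")
    if alt == ref:
        raise ValueError("alternate base equals reference base")
    if ref in "CT":  # collapse to the purine strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}{COMPLEMENT[ref]}>{alt}{COMPLEMENT[alt]}"


def is_transition(mutation_class: str) -> bool:
    return mutation_class in TRANSITIONS


def is_transversion(mutation_class: str) -> bool:
    return mutation_class in SUB_CLASSES and mutation_class not in TRANSITIONS


@dataclass
class Spectrum:
    """Counts per mutation class with normalized proportions."""

    counts: dict

    @property
    def n_mutations(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def proportions(self) -> dict:
        n = self.n_mutations
        if n == 0:
            return {c: 0.0 for c in self.counts}
        return {c: v / n for c, v in self.counts.items()}

    def aggregate(self) -> dict:
        """Transition / transversion / indel proportions."""
        props = self.proportions
        return {
            "transition": sum(props.get(c, 0.0) for c in SUB_CLASSES if is_transition(c)),
            "transversion": sum(props.get(c, 0.0) for c in SUB_CLASSES if is_transversion(c)),
            "indel": props.get(INSERTION, 0.0) + props.get(DELETION, 0.0),
        }

    def as_vector(self, classes: Sequence[str] = ALL_CLASSES) -> np.ndarray:
        return np.array([self.counts.get(c, 0.0) for c in classes], dtype=float)


def build_spectrum(
    calls: Iterable[MutationCall], gene: ReferenceGene, independent_only: bool = True
) -> Spectrum:
    """Tally calls into a spectrum.

    With ``independent_only`` each distinct (sample, event) pair weighs 1
    (recurrent clonal copies ignored); otherwise events weigh their adjusted
    copy count.
    """
    counts = {c: 0.0 for c in ALL_CLASSES}
    seen: set[tuple[str, EventKey]] = set()
    for call in calls:
        cls = classify(gene.base(call.event.position), call.event)
        if independent_only:
            key = (call.sample, call.event)
            if key in seen:
                continue
            seen.add(key)
            counts[cls] += 1.0
        else:
            counts[cls] += call.adjusted_count
    return Spectrum(counts=counts)


def _pearson_chi2(table: np.ndarray) -> tuple[float, int, np.ndarray]:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, df, expected


def compare_spectra(
    spectrum_a: Spectrum,
    spectrum_b: Spectrum,
    n_mc: int = MC_DRAWS,
    seed: int = MC_SEED,
) -> dict:
    """Pearson chi-squared test of independence on the class x group table.

    When any expected cell is below 5 the p-value is computed by Monte-Carlo
    under fixed margins (multivariate hypergeometric row draws, fixed seed).
    """
    if spectrum_a.n_mutations == 0 or spectrum_b.n_mutations == 0:
        raise ValueError("cannot compare an empty spectrum")
    ordered = dict.fromkeys(list(ALL_CLASSES) + list(spectrum_a.counts) + list(spectrum_b.counts))
    classes = [
        c for c in ordered if spectrum_a.counts.get(c, 0) + spectrum_b.counts.get(c, 0) > 0
    ]
    table = np.array(
        [
            [round(spectrum_a.counts.get(c, 0)) for c in classes],
            [round(spectrum_b.counts.get(c, 0)) for c in classes],
        ],
        dtype=np.int64,
    )
    chi2, df, expected = _pearson_chi2(table.astype(float))
    monte_carlo = bool((expected < 5).any())
    if not monte_carlo:
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    else:
        rng = np.random.default_rng(seed)
        col_totals = table.sum(axis=0)
        n_a = int(table[0].sum())
        draws_a = rng.multivariate_hypergeometric(col_totals, n_a, size=n_mc).astype(float)
        draws_b = col_totals[None, :] - draws_a
        exp_a, exp_b = expected[0], expected[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(exp_a > 0, (draws_a - exp_a) ** 2 / exp_a, 0.0).sum(axis=1)
            sim += np.where(exp_b > 0, (draws_b - exp_b) ** 2 / exp_b, 0.0).sum(axis=1)
        p = float((1 + np.sum(sim >= chi2 - 1e-12)) / (1 + n_mc))
    return {"chi2": chi2, "df": df, "p": p, "monte_carlo": monte_carlo}


def compare_classes(
    spectrum_a: Spectrum,
    spectrum_b: Spectrum,
    method: str = "holm",
    alpha: float = 0.05,
    n_mc: int = MC_DRAWS,
    seed: int = MC_SEED,
) -> dict:
    """Per-class 2x2 chi-squared comparisons with multiple-testing correction.

    ``method`` is any statsmodels multipletests method ("holm" default,
    "none" for raw p-values).
    """
    from statsmodels.stats.multitest import multipletests

    n_a, n_b = spectrum_a.n_mutations, spectrum_b.n_mutations
    classes = [
        c for c in ALL_CLASSES if spectrum_a.counts.get(c, 0) + spectrum_b.counts.get(c, 0) > 0
    ]
    raw = {}
    for cls in classes:
        a_in = round(spectrum_a.counts.get(cls, 0))
        b_in = round(spectrum_b.counts.get(cls, 0))
        sub_a = Spectrum(counts={"in": a_in, "out": round(n_a) - a_in})
        sub_b = Spectrum(counts={"in": b_in, "out": round(n_b) - b_in})
        raw[cls] = compare_spectra(sub_a, sub_b, n_mc=n_mc, seed=seed)["p"]
    if method == "none":
        adjusted = dict(raw)
    else:
        reject, p_adj, _, _ = multipletests(list(raw.values()), alpha=alpha, method=method)
        adjusted = dict(zip(raw, p_adj))
    return {
        cls: {"p_raw": raw[cls], "p_adj": adjusted[cls], "significant": adjusted[cls] < alpha}
        for cls in classes
    }


def compare_mutant_frequency(pools: Sequence[SamplePool]) -> dict:
    """Poisson regression of mutant pfu with log(total pfu) offset and group term.

    Returns the treated/control rate ratio with its Wald p-value.  When one
    group has no mutant plaques at all the GLM is degenerate and an exact
    conditional two-sample Poisson test is used instead (flagged).
    """
    import statsmodels.api as sm
    from statsmodels.stats.rates import test_poisson_2indep

    groups = sorted({p.group for p in pools})
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    baseline = "control" if "control" in groups else groups[0]
    other = next(g for g in groups if g != baseline)
    flags = []
    for g in groups:
        if sum(1 for p in pools if p.group == g) < 2:
            flags.append(f"single-animal group {g}: confidence interval unreliable")
    y = np.array([p.mutant_pfu for p in pools], dtype=float)
    exposure = np.array([p.total_pfu for p in pools], dtype=float)
    indicator = np.array([1.0 if p.group == other else 0.0 for p in pools])
    zero_group = any(y[indicator == v].sum() == 0 for v in (0.0, 1.0))
    if zero_group:
        flags.append("a group has zero mutant plaques: exact conditional test used")
        count2 = int(y[indicator == 0.0].sum())
        count1 = int(y[indicator == 1.0].sum())
        expo2 = float(exposure[indicator == 0.0].sum())
        expo1 = float(exposure[indicator == 1.0].sum())
        res = test_poisson_2indep(count1, expo1, count2, expo2, method="exact-cond")
        rate1 = count1 / expo1
        rate2 = count2 / expo2
        ratio = rate1 / rate2 if rate2 > 0 else float("inf")
        return {
            "rate_ratio": ratio,
            "p": float(res.pvalue),
            "method": "exact-cond",
            "flags": flags,
        }
    X = sm.add_constant(indicator)
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(exposure))
    fit = model.fit()
    return {
        "rate_ratio": float(np.exp(fit.params[1])),
        "p": float(fit.pvalues[1]),
        "method": "poisson_glm",
        "flags": flags,
    }


def find_hotspots(
    calls: Iterable[MutationCall], min_independent: int = 4
) -> list[tuple[int, int, int]]:
    """Positions with more than ``min_independent`` independent mutations.

    Independence is per-sample-distinct then summed across samples; the
    total is the sum of adjusted copy counts.  Sorted by independent count
    descending, then position.
    """
    independent: dict[int, set] = {}
    totals: dict[int, int] = {}
    for call in calls:
        pos = call.event.position
        independent.setdefault(pos, set()).add((call.sample, call.event))
        totals[pos] = totals.get(pos, 0) + call.adjusted_count
    rows = [
        (pos, len(events), totals[pos])
        for pos, events in independent.items()
        if len(events) > min_independent
    ]
    return sorted(rows, key=lambda r: (-r[1], r[0]))


def homopolymer_association(
    calls: Iterable[MutationCall],
    runs: Sequence[HomopolymerRun],
    min_run_len: int = 3,
    adjacency_bp: int = 1,
) -> dict:
    """Fraction of indel calls inside or next to homopolymer runs.

    A call counts when its position lies within a run of length
    >= ``min_run_len`` or within ``adjacency_bp`` of either end.
    Substitutions are excluded.  Returns per-kind totals.
    """
    windows = [
        (run.start - adjacency_bp, run.end + adjacency_bp)
        for run in runs
        if run.length >= min_run_len
    ]
    result = {kind: {"n_inside_or_adjacent": 0, "n_total": 0} for kind in (INSERTION, DELETION)}
    for call in calls:
        if call.event.kind not in result:
            continue
        entry = result[call.event.kind]
        entry["n_total"] += 1
        if any(lo <= call.event.position <= hi for lo, hi in windows):
            entry["n_inside_or_adjacent"] += 1
    return result


def power_simulation(
    full_mutation_list: Sequence[str],
    k: int,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    metric: str | Callable = "gof",
    mc_draws: int = 10_000,
) -> float:
    """Power of a k-mutant subsample to reproduce an animal's full spectrum.

    Repeatedly subsample k mutants without replacement from the animal's
    full mutation list; the default metric scores an iteration a success
    when a chi-squared goodness-of-fit of the subsample against the full
    spectrum is NOT significant (Monte-Carlo p >= alpha, null draws by
    multivariate hypergeometric subsampling).  ``metric`` may be a callable
    ``(subsample_counts, full_counts, rng) -> p_value`` for other designs.
    """
    full_mutation_list = list(full_mutation_list)
    n = len(full_mutation_list)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    classes = sorted(set(full_mutation_list))
    full_counts = np.array([full_mutation_list.count(c) for c in classes], dtype=np.int64)
    expected = k * full_counts / n

    if callable(metric):
        successes = 0
        for _ in range(n_iter):
            sub = rng.multivariate_hypergeometric(full_counts, k)
            if metric(sub, full_counts, rng) >= alpha:
                successes += 1
        return successes / n_iter
    if metric != "gof":
        raise ValueError(f"unknown power metric {metric!r}")

    def chi2_of(samples: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(expected > 0, (samples - expected) ** 2 / expected, 0.0)
        return terms.sum(axis=-1)

    null = chi2_of(rng.multivariate_hypergeometric(full_counts, k, size=mc_draws).astype(float))
    successes = 0
    for _ in range(n_iter):
        sub = rng.multivariate_hypergeometric(full_counts, k).astype(float)
        obs = float(chi2_of(sub))
        p = (1 + int(np.sum(null >= obs - 1e-12))) / (1 + mc_draws)
        if p >= alpha:
            successes += 1
    return successes / n_iter


def write_spectrum_tsv(spectra: dict, path) -> None:
    """Spectra per group as TSV (class, count, proportion per group)."""
    with open(path, "w") as handle:
        handle.write("group\tclass\tcount\tproportion\n")
        for group, spectrum in spectra.items():
            props = spectrum.proportions
            for cls in ALL_CLASSES:
                handle.write(
                    f"{group}\t{cls}\t{spectrum.counts.get(cls, 0)!r}\t{props.get(cls, 0.0)!r}\n"
                )


def plot_spectrum(spectra: dict, path) -> None:
    """Grouped bar chart of class proportions (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(ALL_CLASSES))
    width = 0.8 / max(len(spectra), 1)
    for i, (group, spectrum) in enumerate(spectra.items()):
        props = spectrum.proportions
        ax.bar(x + i * width, [props.get(c, 0.0) for c in ALL_CLASSES], width, label=group)
    ax.set_xticks(x + width * (len(spectra) - 1) / 2)
    ax.set_xticklabels(ALL_CLASSES, rotation=45, ha="right")
    ax.set_ylabel("proportion of independent mutations")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
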