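"""End-to-end orchestration: counts -> noise -> calls -> clonality -> report.

A run takes the full panel of per-library count matrices (two PCR replicates
per animal, optionally plus wild-type negative-control libraries), estimates
the shared background across ALL of them, calls mutations per animal at the
configured stringency, calibrates copy counts through the clonality model,
and assembles per-sample and per-group statistics into a deterministic,
JSON-serializable report.  Every derived number in the report is
recomputable from the persisted intermediate TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .calling import (
    MutationCall,
    SamplePool,
    call_mutations,
    calling_threshold,
    concordance_failures,
    tabulate_mutations,
    write_calls_tsv,
)
from .clonality import (
    DEFAULT_MODEL,
    ClonalityModel,
    adjust_count,
    clonality,
    corrected_mutation_frequency,
    fit_lod_linear,
    fold_induction,
)
from .noise import estimate_noise, indel_mask, subtract_noise, write_noise_tsv
from .pileup_counts import PositionCountMatrix, to_proportions
from .reference import ReferenceGene
from .spectrum_stats import (
    Spectrum,
    build_spectrum,
    compare_mutant_frequency,
    compare_spectra,
    write_spectrum_tsv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def run_pipeline(
    pools: list[SamplePool],
    matrices: dict,
    gene: ReferenceGene,
    stringency: float = 1.0,
    model: ClonalityModel | None = None,
    calibration_points=None,
    extra_libraries: list[PositionCountMatrix] | None = None,
    outdir=None,
) -> dict:
    """Run the full analysis and return the report dict.

    ``matrices`` maps animal_id -> (replicate_1, replicate_2) count matrices.
    ``extra_libraries`` (e.g. wild-type controls) join the noise panel but
    are not called.  The clonality model is, in order of preference: the one
    supplied, one fitted from ``calibration_points``, or the package default
    calibration.  With ``outdir`` set, all intermediates are persisted.
    """
    if model is None:
        model = fit_lod_linear(calibration_points) if calibration_points else DEFAULT_MODEL
    for pool in pools:
        if pool.animal_id not in matrices:
            raise PipelineError(f"missing count matrices for sample {pool.animal_id}")
        if len(matrices[pool.animal_id]) != 2:
            raise PipelineError(f"sample {pool.animal_id} needs exactly two replicates")
    for animal, pair in matrices.items():
        for m in pair:
            if m.length != len(gene):
                raise PipelineError(
                    f"library {m.library_id}: length {m.length} does not match reference {len(gene)}"
                )

    panel = [to_proportions(m) for pair in matrices.values() for m in pair]
    panel += [to_proportions(m) for m in (extra_libraries or [])]
    profile = estimate_noise(panel)
    mask = indel_mask(profile)
    logger.info(
        "noise panel: %d libraries, indel cap %.3g, %d indel events masked",
        profile.n_libraries,
        profile.indel_cap,
        len(mask),
    )

    samples: dict[str, dict] = {}
    all_calls: list[MutationCall] = []
    by_group_calls: dict[str, list[MutationCall]] = {}
    by_group_mf: dict[str, list[float]] = {}
    by_group_cmf: dict[str, list[float]] = {}
    prop_cache = {p.library_id: p for p in panel}
    for pool in pools:
        rep1, rep2 = matrices[pool.animal_id]
        true1 = subtract_noise(prop_cache[rep1.library_id], profile)
        true2 = subtract_noise(prop_cache[rep2.library_id], profile)
        calls = call_mutations(
            true1,
            true2,
            n_plaques=pool.n_plaques,
            stringency=stringency,
            indel_mask=mask,
            gene=gene,
            sample=pool.animal_id,
        )
        for c in calls:
            c.adjusted_count = adjust_count(c.raw_count, model)
        removed = concordance_failures(true1, true2, pool.n_plaques, stringency)
        summary = tabulate_mutations(calls, use_adjusted=True)
        clon = clonality(summary["total"], summary["independent"])
        cmf = corrected_mutation_frequency(pool, clon)
        samples[pool.animal_id] = {
            "group": pool.group,
            "n_plaques": pool.n_plaques,
            "threshold": calling_threshold(pool.n_plaques, stringency),
            "independent": summary["independent"],
            "total_raw": sum(c.raw_count for c in calls),
            "total_adjusted": summary["total"],
            "recurrent": summary["recurrent"],
            "clonality": clon,
            "mutant_frequency": pool.mutant_frequency,
            "corrected_mutation_frequency": cmf,
            "concordance_failures": len(removed),
        }
        logger.info(
            "sample %s: %d independent / %d adjusted total calls, %d replicate-discordant events removed",
            pool.animal_id,
            summary["independent"],
            summary["total"],
            len(removed),
        )
        all_calls.extend(calls)
        by_group_calls.setdefault(pool.group, []).extend(calls)
        by_group_mf.setdefault(pool.group, []).append(pool.mutant_frequency)
        by_group_cmf.setdefault(pool.group, []).append(cmf)

    spectra = {
        group: build_spectrum(calls, gene, independent_only=True)
        for group, calls in by_group_calls.items()
    }
    groups_report = {}
    for group in sorted(by_group_mf):
        spectrum = spectra.get(group, Spectrum(counts={}))
        groups_report[group] = {
            "n_samples": len(by_group_mf[group]),
            "spectrum_counts": {k: v for k, v in spectrum.counts.items()},
            "spectrum_proportions": spectrum.proportions,
            "aggregate": spectrum.aggregate() if spectrum.n_mutations else None,
            "mean_mutant_frequency": float(np.mean(by_group_mf[group])),
            "mean_corrected_mutation_frequency": float(np.mean(by_group_cmf[group])),
        }

    comparison: dict = {}
    group_names = sorted(by_group_mf)
    if len(group_names) == 2:
        control, treated = (
            ("control", next(g for g in group_names if g != "control"))
            if "control" in group_names
            else tuple(group_names)
        )
        if spectra[control].n_mutations > 0 and spectra[treated].n_mutations > 0:
            comparison["spectrum"] = compare_spectra(spectra[control], spectra[treated])
        comparison["mutant_frequency"] = compare_mutant_frequency(pools)
        if np.mean(by_group_cmf[control]) > 0:
            comparison["fold_induction"] = fold_induction(
                by_group_cmf[treated], by_group_cmf[control]
            )

    report = {
        "samples": samples,
        "groups": groups_report,
        "comparison": comparison,
        "noise": {
            "n_libraries": profile.n_libraries,
            "indel_cap": profile.indel_cap,
            "n_indel_events_masked": len(mask),
        },
        "clonality_model": {
            "lod": model.lod,
            "slope": model.slope,
            "intercept": model.intercept,
        },
        "provenance": {
            "package_version": __version__,
            "stringency": stringency,
            "config_hash": _config_hash(pools, stringency, model),
        },
    }
    if outdir is not None:
        _persist(outdir, report, profile, mask, all_calls, gene, spectra)
    return report


def _config_hash(pools, stringency, model) -> str:
    payload = json.dumps(
        {
            "pools": [
                [p.animal_id, p.group, p.n_plaques, p.mutant_pfu, p.total_pfu] for p in pools
            ],
            "stringency": stringency,
            "model": [model.lod, model.slope, model.intercept],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _persist(outdir, report, profile, mask, calls, gene, spectra) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_noise_tsv(profile, outdir / "noise_profile.tsv", mask=mask)
    write_calls_tsv(calls, gene, outdir / "calls.tsv")
    write_spectrum_tsv(spectra, outdir / "spectra.tsv")
    (outdir / "report.json").write_text(report_json(report))


def report_json(report: dict) -> str:
    """Deterministic JSON rendering of a report (sorted keys, fixed floats)."""
    return json.dumps(report, sort_keys=True, indent=2, default=float) + "\n"
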