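"""End-to-end orchestration: generate -> extract -> filter -> info -> DFA.

A :class:`RunConfig` (built in code or loaded from YAML) drives a fully
seeded run that writes WAVs, the feature table, and a JSON report
summarizing dataset composition, the filter audit, retained components,
signature information, and the requested discriminant analyses with
Holm-corrected decisions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .profiles import SPECIES_PROFILES
from .synth import HierarchyConfig, realistic_sds, sample_population, write_dataset
from .spectro import FEATURE_COLUMNS, SpectrogramParams, extract_table
from .selection import (double_note_feature_columns, min_notes_filter,
                        select_double_notes, select_first_notes)
from .info import (estimate_vce, parallel_analysis, pca_varimax,
                   signature_information, weighted_variance_attribution)
from .dfa import LinearDFA, PermutedDFA, holm_correction

log = logging.getLogger("callsig")


@dataclass(frozen=True)
class TestPreset:
    """One named discriminant test: what is classified, controlling what,
    on which subset of the data."""

    name: str
    description: str
    kind: str  # "pdfa" or "dfa"
    test_factor: str
    control_factor: str | None = None
    species: str | None = None
    population: str | None = None
    sex: str | None = None
    note_type: str = "first"  # "first" or "double"


def standard_presets() -> dict[str, TestPreset]:
    """The nine standard discriminant tests of the study design."""
    return {p.name: p for p in [
        TestPreset("test1", "species assignment controlling individual",
                   "pdfa", "species", "individual"),
        TestPreset("test2", "species assignment controlling colony",
                   "pdfa", "species", "colony"),
        TestPreset("test3", "sex assignment controlling individual",
                   "pdfa", "sex", "individual", species="Diaemus"),
        TestPreset("test4", "population assignment controlling individual",
                   "pdfa", "population", "individual", species="Desmodus",
                   sex="F"),
        TestPreset("test5", "captive Desmodus individual assignment",
                   "dfa", "individual", species="Desmodus",
                   population="captive"),
        TestPreset("test6", "wild Desmodus individual assignment",
                   "dfa", "individual", species="Desmodus",
                   population="wild"),
        TestPreset("test7", "Desmodus individual assignment controlling "
                   "recording session", "pdfa", "individual", "session",
                   species="Desmodus"),
        TestPreset("test8", "captive Diaemus individual assignment, "
                   "single notes", "dfa", "individual", species="Diaemus"),
        TestPreset("test9", "captive Diaemus individual assignment, "
                   "double notes", "dfa", "individual", species="Diaemus",
                   note_type="double"),
    ]}


@dataclass
class SpeciesBlock:
    """One generated population of one species."""

    profile: str
    population: str = "captive"
    n_colonies: int = 1
    individuals_per_colony: int = 4
    notes_per_individual: int = 60
    n_sessions: int = 1


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "callsig_run"
    species: list[SpeciesBlock] = field(default_factory=lambda: [
        SpeciesBlock("Desmodus", "captive", 1, 4, 60),
        SpeciesBlock("Desmodus", "wild", 4, 1, 60),
        SpeciesBlock("Diaemus", "captive", 1, 4, 60),
    ])
    snr_db: float = 30.0
    sampling_rate_hz: int = 250_000
    window_ms: float = 0.5
    fft_points: int = 512
    search_band_khz: tuple[float, float] = (8.0, 45.0)
    min_notes: int = 45
    min_gap_ms: float = 30.0
    factors: list[str] = field(default_factory=lambda: [
        "species", "colony", "individual"])
    signature_factors: list[str] = field(default_factory=lambda: [
        "colony", "individual"])
    presets: list[str] = field(default_factory=lambda: ["test1", "test5"])
    n_permutations: int = 100
    n_dfa_reps: int = 20
    alpha: float = 0.05
    pa_iterations: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        species = [SpeciesBlock(**blk) for blk in raw.pop("species", [])]
        cfg = cls(**{k: v for k, v in raw.items() if k != "species"})
        if species:
            cfg.species = species
        if isinstance(cfg.search_band_khz, list):
            cfg.search_band_khz = tuple(cfg.search_band_khz)
        return cfg


def generate(config: RunConfig):
    """Sample all configured populations (ground-truth note specs)."""
    specs = []
    for i, blk in enumerate(config.species):
        profile = SPECIES_PROFILES[blk.profile]
        sds = realistic_sds(profile)
        hierarchy = HierarchyConfig(
            n_colonies=blk.n_colonies,
            individuals_per_colony=blk.individuals_per_colony,
            notes_per_individual=blk.notes_per_individual,
            n_sessions=blk.n_sessions,
            snr_db=config.snr_db,
            seed=int(np.random.SeedSequence(
                [config.seed, i]).generate_state(1)[0] % (2**31)),
            **sds)
        specs.extend(sample_population(
            profile, hierarchy, population=blk.population,
            sampling_rate_hz=config.sampling_rate_hz))
    return specs


def _apply_subset(table: pd.DataFrame, preset: TestPreset) -> pd.DataFrame:
    sub = table
    for attr in ("species", "population", "sex"):
        want = getattr(preset, attr)
        if want is not None:
            sub = sub[sub[attr] == want]
    return sub


def run_preset(preset: TestPreset, first_notes: pd.DataFrame,
               all_notes: pd.DataFrame, config: RunConfig,
               seed: int) -> dict:
    """Execute one discriminant test and return a JSON-ready summary."""
    if preset.note_type == "double":
        paired = select_double_notes(_apply_subset(all_notes, preset))
        if paired.empty:
            raise ValueError(f"{preset.name}: no double-note calls in subset")
        feats = paired[double_note_feature_columns(paired)].dropna(axis=1)
        labels = paired
    else:
        labels = _apply_subset(first_notes, preset)
        feats = labels[[c for c in FEATURE_COLUMNS if c in labels.columns]]
        feats = feats.dropna(axis=1)
    valid = feats.notna().all(axis=1)
    feats, labels = feats[valid.to_numpy()], labels[valid.to_numpy()]
    out = {"name": preset.name, "description": preset.description,
           "kind": preset.kind, "n_notes": int(len(feats))}
    if preset.kind == "dfa":
        model = LinearDFA().fit(feats, labels[preset.test_factor])
        res = model.result()
        out.update(cv_rate=res.cv_rate, training_rate=res.training_rate,
                   wilks_lambda=res.wilks_lambda, chi2=res.chi2, df=res.df,
                   p=res.p_value,
                   per_class_rates=res.per_class_rates.round(1).to_dict())
    else:
        control = labels[preset.control_factor].astype(str)
        if preset.control_factor == "session":
            control = labels["individual"].astype(str) + "/" + control
        est = PermutedDFA(n_dfa_reps=config.n_dfa_reps,
                          n_permutations=config.n_permutations,
                          random_state=seed)
        est.fit(feats, labels[preset.test_factor], groups=control)
        out.update(cv_rate=est.observed_cv_rate_,
                   training_rate=est.observed_training_rate_,
                   p=est.p_value_,
                   n_train_per_subject=est.n_train_per_subject_)
    return out


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("generating synthetic populations (seed=%d)", config.seed)
    specs = generate(config)
    annotations = write_dataset(specs, out / "audio", seed=config.seed,
                                sampling_rate_hz=config.sampling_rate_hz)
    log.info("synthesized %d notes into %s", len(annotations), out / "audio")

    params = SpectrogramParams(window_ms=config.window_ms,
                               fft_points=config.fft_points)
    features = extract_table(annotations, out / "audio", params,
                             search_band_khz=config.search_band_khz)
    features.to_csv(out / "features.csv", index=False)
    n_extracted = len(features)
    log.info("extracted %d notes", n_extracted)

    first = select_first_notes(features, config.min_gap_ms)
    filtered, dropped = min_notes_filter(first, config.min_notes)
    if filtered.empty:
        raise RuntimeError(
            f"min_notes_filter (threshold {config.min_notes}) dropped every "
            "individual; increase notes_per_individual or lower the threshold")
    audit = {
        "notes_extracted": n_extracted,
        "first_notes": int(len(first)),
        "dropped_not_first_or_close": n_extracted - int(len(first)),
        "retained_after_min_notes": int(len(filtered)),
        "dropped_individuals": dropped.to_dict("records"),
    }

    feats = filtered[FEATURE_COLUMNS].dropna(axis=1)
    rng = np.random.default_rng(config.seed)
    n_retained = parallel_analysis(feats, n_iterations=config.pa_iterations,
                                   seed=int(rng.integers(2**31)))
    n_retained = max(1, n_retained)
    model = pca_varimax(feats, n_retained)
    scores = model.transform(feats)
    usable_factors = [f for f in config.factors
                      if filtered[f].nunique() >= 2]
    vce = estimate_vce(scores, filtered, usable_factors)
    sig = signature_information(
        vce, [f for f in config.signature_factors if f in vce.factors])
    attribution = weighted_variance_attribution(vce, model)

    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.presets) + 1)
    presets = standard_presets()
    tests = []
    for name, s in zip(config.presets, seeds):
        tests.append(run_preset(presets[name], filtered, features, config,
                                int(s % (2**31))))
    if tests:
        holm = holm_correction([t["p"] for t in tests], config.alpha)
        for t_res, rej in zip(tests, holm["reject"]):
            t_res["holm_reject"] = bool(rej)

    counts = (filtered.groupby(["species", "population", "colony",
                                "individual"], observed=True)
              .size().rename("notes").reset_index())
    report = {
        "version": __version__,
        "seed": config.seed,
        "runtime_s": round(time.time() - t0, 1),
        "dataset": counts.to_dict("records"),
        "filter_audit": audit,
        "pca": {
            "n_retained": n_retained,
            "variance_proportions": model.variance_proportion_.round(4).tolist(),
            "total_variance_explained_pct": round(
                100 * float(model.variance_proportion_.sum()), 1),
        },
        "variance_components": {
            "factors": vce.factors,
            "between": vce.between.round(4).to_dict("list"),
            "within": vce.within.round(4).tolist(),
        },
        "signature_information": {
            "per_component_bits": sig.h_bits.round(3).tolist(),
            "total_bits": round(sig.total_bits, 3),
            "repeatability": sig.repeatability.round(3).tolist(),
            "mean_repeatability": round(sig.mean_repeatability, 3),
            "signature_factors": sig.signature_factors,
        },
        "variance_attribution_pct": {k: round(v, 1)
                                     for k, v in attribution.items()},
        "tests": tests,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("report written to %s (%.1f s)", out / "report.json",
             report["runtime_s"])
    return report


def config_to_dict(config: RunConfig) -> dict:
    return asdict(config)
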