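"""Synthetic FFPE miRNA-array cohorts with controllable analytical effects.

The generator emulates the statistical structure of probe-level data from a
small-RNA microarray run on formalin-fixed lung-tumour specimens:

* a lognormal signal model on the log2 scale — each measurement probe set
  carries a cohort-level baseline (expressed sets high, the rest at
  background level), a per-sample biological deviation, additive
  probe-level noise, and a dedicated panel of anti-genomic background
  probes;
* a planted prognostic signature: ``n_signature`` human probe sets shifted
  by ``effect_delta`` log2 units in the recurrence class, with exponential
  event times for recurrences and uniformly spread censoring (at least
  ``min_followup_months``) for the rest;
* analytical conditions — RNA input amount scales the above-background
  signal linearly and inflates probe noise at low input, and each probe
  additionally carries a fixed sensitivity to log2 input deviation (this
  probe×input interaction is what makes self-self correlations decay with
  the input *ratio* rather than with the absolute noise level); ATP-mix
  dilution and chip lot add replicate noise only (null conditions by
  construction); the HighPure extraction kit multiplies above-background
  signal by ``extraction_hp_scale`` with fixed per-probe offsets; the old
  FlashTag labeling kit compresses above-background signal toward
  background by ``labeling_f_compression`` with its own per-probe offsets.
  Kit offsets and input sensitivities are drawn once per cohort and shared
  across arrays, which is what lets a principal-component analysis separate
  kits while preserving within-kit sample structure.

Default dimensions (2,000 human + 500 other probe sets, 4 probes each, 200
background probes) are a desk-scale stand-in for the real array; the
intensity defaults are calibrated so that a default-condition array shows
mean signal ≈ 349, mean background ≈ 89 and ≈ 2.4k detected probe sets out
of 2.5k — the magnitudes a well-behaved 600 ng hybridization shows.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` streams, so any subset of the output
(including condition replicates rendered later) is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_io import (
    EXTRACTION_KITS,
    LABELING_KITS,
    IntensityMatrix,
    ProbeAnnotation,
    SampleSheet,
)

REFERENCE_INPUT_NG = 600.0
REFERENCE_ATP = "1:50"
REFERENCE_LOT = "L1"
REFERENCE_EXTRACTION = "RA"
REFERENCE_LABELING = "FH"
CENSOR_WINDOW_MONTHS = 36.0
_INTENSITY_FLOOR = 1e-3  # scanner floor; keeps affine kit transforms positive

# stream identifiers for the counter-based seeding scheme
_STREAM_STRUCTURE = 0
_STREAM_KIT = 1
_STREAM_SAMPLE = 2
_STREAM_ARRAY = 3
_STREAM_REPLICATE = 4


class SimulationError(ValueError):
    """Raised when a configuration invariant is violated."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with calibrated defaults.

    Intensity parameters are on the log2 scale unless stated otherwise;
    ``hazard_recurrence`` is in events/month.
    """

    n_probesets: int = 2500
    probes_per_set: int = 4
    n_background_probes: int = 200
    frac_human: float = 0.8
    frac_expressed: float = 0.92
    expressed_log2_mean: float = 8.0
    expressed_log2_sd: float = 0.8
    background_log2_mean: float = 6.45
    background_log2_sd: float = 0.25
    bio_log2_sd: float = 1.0
    input_response_slope: float = 0.0002  # linear signal factor per ng around 600
    noise_log2_sd_base: float = 0.25
    noise_input_coeff: float = 1.0  # extra noise sd = coeff / sqrt(input_ng)
    input_sensitivity_sd: float = 0.15  # per-probe log2 response per doubling of input
    extraction_hp_scale: float = 0.72
    extraction_probe_sd: float = 0.3
    labeling_f_compression: float = 0.24
    labeling_probe_sd: float = 2.0
    n_signature: int = 12
    effect_delta: float = 1.5
    p_recurrence: float = 0.5
    hazard_recurrence: float = 1.0 / 24.0
    min_followup_months: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_human", "frac_expressed", "p_recurrence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "expressed_log2_sd",
            "background_log2_sd",
            "bio_log2_sd",
            "noise_log2_sd_base",
            "extraction_hp_scale",
            "extraction_probe_sd",
            "labeling_probe_sd",
            "hazard_recurrence",
        ):
            v = getattr(self, name)
            if v <= 0:
                raise SimulationError(f"{name} must be > 0, got {v}")
        for name in ("n_probesets", "probes_per_set", "n_background_probes"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be a positive count")
        if not 0.0 < self.labeling_f_compression <= 1.0:
            raise SimulationError(
                "labeling_f_compression must be in (0, 1], got "
                f"{self.labeling_f_compression}"
            )
        if self.n_signature > int(round(self.n_probesets * self.frac_human)):
            raise SimulationError(
                "n_signature exceeds the number of human probe sets "
                f"({self.n_signature} > {int(round(self.n_probesets * self.frac_human))})"
            )
        if self.noise_input_coeff < 0 or self.input_sensitivity_sd < 0:
            raise SimulationError("noise coefficients must be >= 0")
        if self.min_followup_months < 0:
            raise SimulationError("min_followup_months must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from JSON; unknown keys are rejected."""
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SimulationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the ground truth behind it.

    ``truth`` holds the planted signature probe-set ids, the per-sample
    class labels, and the latent per-probe-set log2 means per sample.
    The private ``_state`` carries the cohort-level random draws needed to
    re-render a sample under perturbed analytical conditions.
    """

    intensities: IntensityMatrix
    annotation: ProbeAnnotation
    samples: SampleSheet
    truth: dict
    _state: dict = dataclasses.field(repr=False, default_factory=dict)

    @property
    def config(self) -> SimulationConfig:
        return self._state["config"]

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.truth["labels"], dtype=int)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _build_annotation(config: SimulationConfig) -> tuple[ProbeAnnotation, dict]:
    n_human = int(round(config.n_probesets * config.frac_human))
    set_ids = [f"PS{i:05d}" for i in range(config.n_probesets)]
    species = ["human"] * n_human + ["other"] * (config.n_probesets - n_human)
    rows = []
    for s, sp in zip(set_ids, species):
        for j in range(config.probes_per_set):
            rows.append((f"{s}_p{j}", s, sp, "measurement"))
    for b in range(config.n_background_probes):
        pid = f"BG{b:05d}"
        rows.append((pid, pid, "other", "background"))
    table = pd.DataFrame(rows, columns=["probe_id", "probeset_id", "species", "role"])
    layout = {
        "set_ids": np.array(set_ids),
        "n_human": n_human,
        # measurement probes come first, in blocks of probes_per_set
        "probe_set_index": np.repeat(
            np.arange(config.n_probesets), config.probes_per_set
        ),
        "n_measurement": config.n_probesets * config.probes_per_set,
    }
    return ProbeAnnotation(table), layout


def _render_array(
    state: Mapping,
    sample_index: int,
    rna_input_ng: float,
    extraction_kit: str,
    labeling_kit: str,
    noise_rng: np.random.Generator,
) -> np.ndarray:
    """Render one hybridization of a sample's latent profile.

    ATP dilution and chip lot intentionally do not appear: they contribute
    replicate noise only (fresh draws from ``noise_rng``), mirroring assays
    where those conditions showed no systematic effect.
    """
    config: SimulationConfig = state["config"]
    layout = state["layout"]
    latent_sets = state["latent"][:, sample_index]  # log2 mean per probe set

    u = np.log2(rna_input_ng / REFERENCE_INPUT_NG)
    noise_sd = np.sqrt(
        config.noise_log2_sd_base**2 + (config.noise_input_coeff**2) / rna_input_ng
    )
    n_meas = layout["n_measurement"]
    log2sig = (
        latent_sets[layout["probe_set_index"]]
        + state["input_sens"] * u
        + noise_rng.normal(0.0, noise_sd, size=n_meas)
    )
    lin = np.exp2(log2sig)
    input_factor = max(
        0.05, 1.0 + config.input_response_slope * (rna_input_ng - REFERENCE_INPUT_NG)
    )
    lin *= input_factor

    bg_lin = float(2.0**config.background_log2_mean)
    if extraction_kit == "HP":
        lin = bg_lin + config.extraction_hp_scale * state["extraction_offsets"] * (
            lin - bg_lin
        )
    elif extraction_kit != REFERENCE_EXTRACTION:
        raise SimulationError(f"unknown extraction_kit level: {extraction_kit!r}")
    if labeling_kit == "F":
        lin = bg_lin + config.labeling_f_compression * state["labeling_offsets"] * (
            lin - bg_lin
        )
    elif labeling_kit != REFERENCE_LABELING:
        raise SimulationError(f"unknown labeling_kit level: {labeling_kit!r}")
    lin = np.maximum(lin, _INTENSITY_FLOOR)

    bg_sd = np.sqrt(config.background_log2_sd**2 + config.noise_log2_sd_base**2)
    background = np.exp2(
        noise_rng.normal(config.background_log2_mean, bg_sd, config.n_background_probes)
    )
    return np.concatenate([lin, background])


def generate_cohort(config: SimulationConfig, n_samples: int) -> SyntheticCohort:
    """Generate a cohort of ``n_samples`` default-condition hybridizations.

    Every sample is rendered once at the reference analytical condition
    (600 ng input, RA extraction, FH labeling, ATP 1:50, reference lot).
    Recurrence labels are Bernoulli(``p_recurrence``); recurrence cases get
    exponential event times, the rest are censored beyond the minimum
    follow-up. Identical seed + config give a bit-identical cohort.
    """
    if not isinstance(config, SimulationConfig):
        raise SimulationError("config must be a SimulationConfig")
    if n_samples < 4:
        raise SimulationError(f"n_samples must be >= 4, got {n_samples}")

    annotation, layout = _build_annotation(config)
    seed = config.seed

    rng_struct = _rng(seed, _STREAM_STRUCTURE)
    expressed = rng_struct.random(config.n_probesets) < config.frac_expressed
    baseline = np.where(
        expressed,
        rng_struct.normal(
            config.expressed_log2_mean, config.expressed_log2_sd, config.n_probesets
        ),
        rng_struct.normal(
            config.background_log2_mean, config.background_log2_sd, config.n_probesets
        ),
    )
    # signature drawn among *expressed* human probe sets so the planted
    # effect is never hidden below background
    human_expressed = np.flatnonzero(expressed[: layout["n_human"]])
    if len(human_expressed) < config.n_signature:
        raise SimulationError(
            "n_signature exceeds the number of expressed human probe sets"
        )
    signature_idx = np.sort(
        rng_struct.choice(human_expressed, size=config.n_signature, replace=False)
    )

    rng_kit = _rng(seed, _STREAM_KIT)
    n_meas = layout["n_measurement"]

    def _offset_multipliers(sd: float) -> np.ndarray:
        # kit chemistry acts on the RNA species, so offsets are drawn per
        # probe set and broadcast to its probes; lognormal factors are
        # normalized to mean 1 so the kit-level scale/compression constants
        # stay interpretable as mean ratios
        m = np.exp2(rng_kit.normal(0.0, sd, config.n_probesets))
        m /= np.exp((sd * np.log(2.0)) ** 2 / 2.0)
        return m[layout["probe_set_index"]]

    state = {
        "config": config,
        "layout": layout,
        "input_sens": rng_kit.normal(0.0, config.input_sensitivity_sd, n_meas),
        "extraction_offsets": _offset_multipliers(config.extraction_probe_sd),
        "labeling_offsets": _offset_multipliers(config.labeling_probe_sd),
    }

    rng_sample = _rng(seed, _STREAM_SAMPLE)
    labels = (rng_sample.random(n_samples) < config.p_recurrence).astype(int)
    bio = rng_sample.normal(0.0, config.bio_log2_sd, (config.n_probesets, n_samples))
    latent = baseline[:, None] + bio
    latent[signature_idx[:, None], np.flatnonzero(labels == 1)[None, :]] += (
        config.effect_delta
    )
    state["latent"] = latent

    times = np.empty(n_samples)
    events = np.empty(n_samples, dtype=int)
    for i in range(n_samples):
        if labels[i] == 1:
            times[i] = rng_sample.exponential(1.0 / config.hazard_recurrence)
            events[i] = 1
        else:
            times[i] = config.min_followup_months + rng_sample.uniform(
                0.0, CENSOR_WINDOW_MONTHS
            )
            events[i] = 0

    columns = {}
    for i in range(n_samples):
        noise_rng = _rng(seed, _STREAM_ARRAY, i)
        columns[f"A{i:03d}"] = _render_array(
            state, i, REFERENCE_INPUT_NG, REFERENCE_EXTRACTION, REFERENCE_LABELING,
            noise_rng,
        )
    values = pd.DataFrame(columns, index=annotation.probe_ids)
    intensities = IntensityMatrix(values)

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "array_id": [f"A{i:03d}" for i in range(n_samples)],
                "sample_id": [f"S{i:03d}" for i in range(n_samples)],
                "rna_input_ng": REFERENCE_INPUT_NG,
                "atp_dilution": REFERENCE_ATP,
                "lot_id": REFERENCE_LOT,
                "extraction_kit": REFERENCE_EXTRACTION,
                "labeling_kit": REFERENCE_LABELING,
                "recurrence": labels.astype(float),
                "time_months": times,
                "event": events.astype(float),
            }
        )
    )

    truth = {
        "signature_ids": [str(s) for s in layout["set_ids"][signature_idx]],
        "labels": labels.tolist(),
        "latent": pd.DataFrame(
            latent, index=layout["set_ids"], columns=[f"S{i:03d}" for i in range(n_samples)]
        ),
    }
    return SyntheticCohort(intensities, annotation, sheet, truth, state)


_CONDITION_COVARIATES = (
    "rna_input_ng",
    "atp_dilution",
    "lot_id",
    "extraction_kit",
    "labeling_kit",
)


def _validate_condition(spec: Mapping) -> tuple[str, object]:
    if len(spec) != 1:
        raise SimulationError(
            f"each condition-spec must vary exactly one covariate, got {dict(spec)}"
        )
    (cov, level), = spec.items()
    if cov not in _CONDITION_COVARIATES:
        raise SimulationError(
            f"unknown covariate {cov!r}; allowed: {_CONDITION_COVARIATES}"
        )
    if cov == "rna_input_ng":
        level = float(level)
        if level <= 0:
            raise SimulationError("rna_input_ng must be > 0")
    elif cov == "extraction_kit" and level not in EXTRACTION_KITS:
        raise SimulationError(
            f"unknown extraction_kit level {level!r}; allowed {EXTRACTION_KITS}"
        )
    elif cov == "labeling_kit" and level not in LABELING_KITS:
        raise SimulationError(
            f"unknown labeling_kit level {level!r}; allowed {LABELING_KITS}"
        )
    elif cov == "atp_dilution":
        level = str(level)
        parts = level.split(":")
        if len(parts) != 2 or not all(p.strip().isdigit() for p in parts):
            raise SimulationError(f"atp_dilution must look like '1:50', got {level!r}")
    return cov, level


def generate_condition_replicates(
    cohort: SyntheticCohort,
    sample_id: str,
    conditions: Sequence[Mapping],
) -> tuple[IntensityMatrix, SampleSheet]:
    """Re-render one sample's latent profile under varied analytical conditions.

    Each condition-spec is a one-entry mapping naming the varied covariate
    and its level, e.g. ``{"rna_input_ng": 80}`` or ``{"labeling_kit": "F"}``.
    The latent expression is held fixed; only the analytical rendering (and
    fresh replicate noise, seeded deterministically per replicate slot)
    changes. Varying ATP dilution or lot adds replicate noise only.
    """
    sample_ids = cohort.samples.table["sample_id"].tolist()
    if sample_id not in sample_ids:
        raise SimulationError(f"unknown sample_id: {sample_id!r}")
    sample_index = sample_ids.index(sample_id)
    config = cohort.config

    columns = {}
    rows = []
    base = cohort.samples.table.iloc[sample_index]
    for r, spec in enumerate(conditions):
        cov, level = _validate_condition(spec)
        covs = {
            "rna_input_ng": REFERENCE_INPUT_NG,
            "atp_dilution": REFERENCE_ATP,
            "lot_id": REFERENCE_LOT,
            "extraction_kit": REFERENCE_EXTRACTION,
            "labeling_kit": REFERENCE_LABELING,
        }
        covs[cov] = level
        # replicate slot seeded by (sample, slot, condition) so a repeated
        # identical call is bit-identical while distinct slots differ
        cond_key = zlib.crc32(f"{cov}={level}".encode()) & 0x7FFFFFFF
        noise_rng = _rng(config.seed, _STREAM_REPLICATE, sample_index, r, cond_key)
        col = _render_array(
            cohort._state,
            sample_index,
            float(covs["rna_input_ng"]),
            str(covs["extraction_kit"]),
            str(covs["labeling_kit"]),
            noise_rng,
        )
        array_id = f"{sample_id}.r{r}.{cov}={level}"
        columns[array_id] = col
        rows.append(
            {
                "array_id": array_id,
                "sample_id": sample_id,
                "rna_input_ng": float(covs["rna_input_ng"]),
                "atp_dilution": covs["atp_dilution"],
                "lot_id": covs["lot_id"],
                "extraction_kit": covs["extraction_kit"],
                "labeling_kit": covs["labeling_kit"],
                "recurrence": base["recurrence"],
                "time_months": base["time_months"],
                "event": base["event"],
            }
        )
    values = pd.DataFrame(columns, index=cohort.annotation.probe_ids)
    return IntensityMatrix(values), SampleSheet(pd.DataFrame(rows))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write intensities.tsv, annotation.tsv, samples.tsv and truth.json."""
    from . import array_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    array_io.write_intensity_table(cohort.intensities, out / "intensities.tsv")
    array_io.write_probe_annotation(cohort.annotation, out / "annotation.tsv")
    array_io.write_sample_sheet(cohort.samples, out / "samples.tsv")
    truth = {
        "signature_ids": cohort.truth["signature_ids"],
        "labels": cohort.truth["labels"],
        "config": cohort.config.to_dict(),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
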