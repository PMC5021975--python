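"""Synthetic two-institution EHR cohorts with known birth-month disease effects.

Each patient draws a birth month from a configurable (default uniform)
12-point distribution, a birth year uniformly in a window (default
1926–2000), and category labels for each demographic attribute. Disease
status for each condition is an independent Bernoulli draw whose probability
depends on the patient's birth month through a multiplicative effect curve:

    cosine shape:  p(m) = p0 * (1 + A * cos(2*pi*(m - phi) / 12))

with marginal prevalence ``p0`` under uniform births (the cosine averages to
zero over a full year), amplitude ``A`` in [0, 1), and peak month ``phi``
(1 = January .. 12 = December). A ``custom`` shape substitutes any
non-negative 12-point multiplier curve with mean 1. The effect acts
multiplicatively on probability (not log-odds), so the injected curve is
directly comparable to the relative-risk scale the scan estimates.

Null conditions have month-independent prevalence cycled deterministically
through the grid {0.001, 0.005, 0.01, 0.05, 0.1}, spanning both sides of the
usual 1000-case inclusion threshold at realistic cohort sizes.

The two-institution generator supports three designs: ``shared`` (identical
effect specs at both sites, patients drawn independently), ``independent``
(the second site redraws each condition's peak month uniformly on 1..12 and
amplitude uniformly on [0.02, 0.15]), and ``null`` (all amplitudes zero at
both sites).

Everything is deterministic given the spec and seed: identical inputs
reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import derive_seed
from .ingest import PatientRecord

NULL_PREVALENCE_GRID = (0.001, 0.005, 0.01, 0.05, 0.1)
INDEPENDENT_AMPLITUDE_RANGE = (0.02, 0.15)
DEFAULT_BIRTH_YEAR_RANGE = (1926, 2000)
#: single default demographic attribute, at large-urban-hospital-like proportions
DEFAULT_DEMOGRAPHICS = (("sex", ("female", "male", "other"), (0.58, 0.4197, 0.0003)),)

_MONTHS = np.arange(1, 13)


def _check_probs(probs, what: str, length: int | None = None) -> tuple[float, ...]:
    p = np.asarray(probs, dtype=float)
    if length is not None and p.shape != (length,):
        raise ValueError(f"{what} must have length {length}")
    if (p < 0).any():
        raise ValueError(f"{what} entries must be non-negative")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError(f"{what} must sum to 1 (got {p.sum()!r})")
    return tuple(float(x) for x in p)


@dataclass(frozen=True)
class PopulationSpec:
    """Population to simulate: size, birth-month/year marginals, demographics."""

    n_patients: int
    birth_month_probs: tuple[float, ...] = tuple([1.0 / 12] * 12)
    birth_year_range: tuple[int, int] = DEFAULT_BIRTH_YEAR_RANGE
    demographic_specs: tuple = DEFAULT_DEMOGRAPHICS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        object.__setattr__(
            self, "birth_month_probs",
            _check_probs(self.birth_month_probs, "birth_month_probs", 12),
        )
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ValueError("birth_year_range low must be <= high")
        object.__setattr__(self, "birth_year_range", (int(lo), int(hi)))
        specs = []
        for name, labels, probs in self.demographic_specs:
            labels = tuple(str(x) for x in labels)
            probs = _check_probs(probs, f"demographic {name!r} probabilities", len(labels))
            specs.append((str(name), labels, probs))
        object.__setattr__(self, "demographic_specs", tuple(specs))


@dataclass(frozen=True)
class EffectSpec:
    """Ground truth for one condition: prevalence, amplitude, peak month, shape."""

    condition_code: str
    prevalence_p0: float
    amplitude_A: float
    peak_month_phi: int = 1
    shape: str = "cosine"
    custom_curve: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_p0 <= 1.0:
            raise ValueError("prevalence_p0 must be a probability")
        if not 0.0 <= self.amplitude_A < 1.0:
            raise ValueError("amplitude_A must lie in [0, 1)")
        if self.peak_month_phi not in range(1, 13):
            raise ValueError("peak_month_phi must be an integer in 1..12")
        if self.shape not in ("cosine", "custom"):
            raise ValueError('shape must be "cosine" or "custom"')
        if self.shape == "custom":
            if self.custom_curve is None:
                raise ValueError("custom shape requires custom_curve")
            curve = np.asarray(self.custom_curve, dtype=float)
            if curve.shape != (12,):
                raise ValueError("custom_curve must have length 12")
            if (curve < 0).any():
                raise ValueError("custom_curve multipliers must be non-negative")
            if abs(curve.mean() - 1.0) > 1e-9:
                raise ValueError("custom_curve must have mean 1")
            object.__setattr__(self, "custom_curve", tuple(float(x) for x in curve))
        probs = self.monthly_probs()
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError(
                f"effect {self.condition_code!r}: monthly probability outside [0, 1]"
            )

    def multiplier_curve(self) -> np.ndarray:
        """The 12 monthly risk multipliers (mean 1 under uniform births)."""
        if self.shape == "cosine":
            return 1.0 + self.amplitude_A * np.cos(
                2.0 * np.pi * (_MONTHS - self.peak_month_phi) / 12.0
            )
        return np.asarray(self.custom_curve, dtype=float)

    def monthly_probs(self) -> np.ndarray:
        """Per-birth-month disease probabilities ``p0 * multiplier``."""
        return self.prevalence_p0 * self.multiplier_curve()


@dataclass
class InstitutionDataset:
    """One institution's simulated cohort plus its ground-truth effect specs."""

    institution_label: str
    patients: list[PatientRecord]
    truth: list[EffectSpec]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient identifiers must be unique within a dataset")
        present: set[str] = set()
        for p in self.patients:
            present.update(p.condition_codes)
        self.metadata.setdefault(
            "zero_case_codes",
            sorted(e.condition_code for e in self.truth if e.condition_code not in present),
        )


def _null_specs(n: int) -> list[EffectSpec]:
    return [
        EffectSpec(
            condition_code=f"NULL{i:04d}",
            prevalence_p0=NULL_PREVALENCE_GRID[i % len(NULL_PREVALENCE_GRID)],
            amplitude_A=0.0,
        )
        for i in range(n)
    ]


def generate_cohort(
    pop: PopulationSpec,
    effects: list[EffectSpec],
    null_conditions: int = 0,
    seed: int | None = None,
    institution_label: str = "site",
) -> InstitutionDataset:
    """Simulate one institution's cohort.

    Birth months, years and demographics are drawn independently per patient;
    each condition's disease status is Bernoulli at the effect curve's
    probability for the patient's birth month. ``null_conditions`` extra
    month-independent conditions are appended with prevalences cycled through
    :data:`NULL_PREVALENCE_GRID`. The explicit ``seed`` argument overrides
    ``pop.seed`` when given. Identical inputs reproduce identical output.
    """
    if null_conditions < 0:
        raise ValueError("null_conditions must be >= 0")
    if seed is None:
        seed = pop.seed
    all_effects = list(effects) + _null_specs(null_conditions)
    codes = [e.condition_code for e in all_effects]
    if len(codes) != len(set(codes)):
        raise ValueError("condition codes must be unique across effects")

    rng = np.random.default_rng(seed)
    n = pop.n_patients
    months = rng.choice(12, size=n, p=np.asarray(pop.birth_month_probs)) + 1
    lo, hi = pop.birth_year_range
    years = rng.integers(lo, hi + 1, size=n)
    demo_draws = {}
    for name, labels, probs in pop.demographic_specs:
        idx = rng.choice(len(labels), size=n, p=np.asarray(probs))
        demo_draws[name] = np.asarray(labels, dtype=object)[idx]

    # disease status, one vectorized Bernoulli sweep per condition
    codes_by_patient: dict[int, set[str]] = {}
    for spec in all_effects:
        p_by_month = spec.monthly_probs()
        hits = np.flatnonzero(rng.random(n) < p_by_month[months - 1])
        for i in hits:
            codes_by_patient.setdefault(int(i), set()).add(spec.condition_code)

    # plain-list indexing: building n dataclass records dominates runtime,
    # and per-element numpy scalar access is an order of magnitude slower
    years_l = years.tolist()
    months_l = months.tolist()
    demo_cols = [(name, demo_draws[name].tolist()) for name, _, _ in pop.demographic_specs]
    get_codes = codes_by_patient.get
    patients = [
        PatientRecord(
            patient_id=f"P{i:07d}",
            birth_year=years_l[i],
            birth_month=months_l[i],
            demographics={name: col[i] for name, col in demo_cols},
            condition_codes=get_codes(i) or set(),
        )
        for i in range(n)
    ]
    return InstitutionDataset(
        institution_label=institution_label,
        patients=patients,
        truth=all_effects,
        metadata={"seed": int(seed), "n_patients": n},
    )


def generate_pair(
    shared: list[EffectSpec],
    mode: str,
    pops: tuple[PopulationSpec, PopulationSpec],
    seed: int = 0,
    null_conditions: int = 0,
    labels: tuple[str, str] = ("site_a", "site_b"),
) -> tuple[InstitutionDataset, InstitutionDataset]:
    """Simulate a two-institution design.

    ``shared``: both sites use identical effect specs (patients still drawn
    independently). ``independent``: the second site redraws each condition's
    peak month uniformly on 1..12 and its amplitude uniformly on
    [0.02, 0.15]. ``null``: all amplitudes forced to zero at both sites.
    Ground truth for both sites is returned with the datasets.
    """
    if mode not in ("shared", "independent", "null"):
        raise ValueError('mode must be "shared", "independent" or "null"')
    if mode == "shared" and not shared:
        raise ValueError("shared mode requires a non-empty effect list")

    if mode == "shared":
        truth_a, truth_b = list(shared), list(shared)
    elif mode == "independent":
        prior_rng = np.random.default_rng(derive_seed(seed, "independent-prior"))
        truth_a = list(shared)
        truth_b = [
            dataclasses.replace(
                e,
                peak_month_phi=int(prior_rng.integers(1, 13)),
                amplitude_A=float(prior_rng.uniform(*INDEPENDENT_AMPLITUDE_RANGE)),
                shape="cosine",
                custom_curve=None,
            )
            for e in shared
        ]
    else:  # null
        truth_a = [
            dataclasses.replace(e, amplitude_A=0.0, shape="cosine", custom_curve=None)
            for e in shared
        ]
        truth_b = list(truth_a)

    if [e.condition_code for e in truth_a] != [e.condition_code for e in truth_b]:
        raise ValueError("condition code lists differ between the two truth sets")

    ds_a = generate_cohort(
        pops[0], truth_a, null_conditions, derive_seed(seed, "cohort", labels[0]), labels[0]
    )
    ds_b = generate_cohort(
        pops[1], truth_b, null_conditions, derive_seed(seed, "cohort", labels[1]), labels[1]
    )
    return ds_a, ds_b


def write_dataset(ds: InstitutionDataset, directory) -> dict[str, Path]:
    """Write a dataset as ``patients.csv``, ``diagnoses.csv`` and ``truth.csv``.

    ``patients.csv`` has header ``patient_id,birth_year,birth_month`` followed
    by one column per demographic attribute; ``diagnoses.csv`` one row per
    (patient, condition) with vocabulary ``SNOMED``; ``truth.csv`` one row per
    simulated condition (custom multiplier curves are recorded by shape name
    only). Files round-trip losslessly through :func:`seawas.ingest.read_patients`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": directory / "patients.csv",
        "diagnoses": directory / "diagnoses.csv",
        "truth": directory / "truth.csv",
    }

    demo_names: list[str] = []
    for p in ds.patients:
        for name in p.demographics:
            if name not in demo_names:
                demo_names.append(name)
    patient_rows = {
        "patient_id": [p.patient_id for p in ds.patients],
        "birth_year": [p.birth_year for p in ds.patients],
        "birth_month": [p.birth_month for p in ds.patients],
    }
    for name in demo_names:
        patient_rows[name] = [p.demographics.get(name, "") for p in ds.patients]
    pd.DataFrame(patient_rows).to_csv(paths["patients"], index=False, lineterminator="\n")

    dx_rows = [
        (p.patient_id, code, "SNOMED")
        for p in ds.patients
        for code in sorted(p.condition_codes)
    ]
    pd.DataFrame(dx_rows, columns=["patient_id", "code", "vocabulary"]).to_csv(
        paths["diagnoses"], index=False, lineterminator="\n"
    )

    pd.DataFrame(
        [
            (e.condition_code, e.prevalence_p0, e.amplitude_A, e.peak_month_phi, e.shape)
            for e in ds.truth
        ],
        columns=["condition_code", "prevalence_p0", "amplitude_A", "peak_month_phi", "shape"],
    ).to_csv(paths["truth"], index=False, lineterminator="\n")
    return paths


# -- config plumbing ---------------------------------------------------------

def population_spec_from_dict(d: dict) -> PopulationSpec:
    """Build a PopulationSpec from a config mapping (YAML/JSON field names)."""
    demo = d.get("demographic_specs", d.get("demographics"))
    kwargs = {"n_patients": int(d["n_patients"])}
    if "birth_month_probs" in d:
        kwargs["birth_month_probs"] = tuple(d["birth_month_probs"])
    if "birth_year_range" in d:
        kwargs["birth_year_range"] = tuple(d["birth_year_range"])
    if demo is not None:
        specs = []
        for item in demo:
            if isinstance(item, dict):
                specs.append((item["name"], tuple(item["categories"]), tuple(item["probs"])))
            else:
                name, labels, probs = item
                specs.append((name, tuple(labels), tuple(probs)))
        kwargs["demographic_specs"] = tuple(specs)
    if "seed" in d:
        kwargs["seed"] = int(d["seed"])
    return PopulationSpec(**kwargs)


def effect_spec_from_dict(d: dict) -> EffectSpec:
    """Build an EffectSpec from a config mapping (YAML/JSON field names)."""
    return EffectSpec(
        condition_code=str(d["condition_code"]),
        prevalence_p0=float(d["prevalence_p0"]),
        amplitude_A=float(d["amplitude_A"]),
        peak_month_phi=int(d.get("peak_month_phi", 1)),
        shape=str(d.get("shape", "cosine")),
        custom_curve=tuple(d["custom_curve"]) if d.get("custom_curve") else None,
    )


def load_config(path) -> dict:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
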