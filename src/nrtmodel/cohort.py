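"""Synthetic implanted-cohort generator.

Emulates a per-electrode NRT-threshold dataset from a cochlear-implant
clinic: 31 subjects by default, 22 contacts each, with subject-level cochlear
geometry, array type and scalar placement, electrode-level impedance and
electrode-modiolus distance, demographics, and an NRT threshold built as::

    NRT_ij = intercept + s(CNF_ij) + beta_imp * imp_ij^2 + beta_dist * d_ij^2
             + beta_ST * 1[ST] + array + etiology + age terms + b_i + e_ij

with a subject random intercept ``b_i ~ N(0, sigma_b^2)`` and residual
``e_ij ~ N(0, sigma_e^2)`` — the generative mirror of the random-intercept
mixed model the pipeline fits, so parameter recovery is a like-for-like
check.  Thresholds are rounded to integer current levels and clipped to the
device range [0, 255].

Default effect sizes are the multivariate (adjusted) estimates of the source
cohort; the intercept and the two variance components are calibrated (see
:func:`calibrate_config`) so that a large generated cohort reproduces the
reported grand mean (169.68 C.L.), within-subject SD (13.66) and
between-subject SD (18.60) after the covariates have claimed their share of
the spread.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .splines import SplineBasisSpec, build_spline_basis, spline_column_names

__all__ = [
    "SplineShape",
    "GeneratorConfig",
    "default_config",
    "default_double_bump_shape",
    "flat_shape",
    "generate_cohort",
    "summarize_cohort",
    "calibrate_config",
    "proportional_counts",
]

ETIOLOGY_LEVELS = (
    "progressive_snhl",
    "genetic",
    "autoimmune",
    "ototoxic",
    "otosclerosis",
    "viral",
)


@dataclass(frozen=True)
class SplineShape:
    """A mean threshold-vs-frequency profile on the truncated-power basis:
    ``s(f) = const + basis(f) @ coefs`` with coefficients in C.L. per
    Hz-power unit."""

    const: float
    coefs: tuple[float, ...]
    basis: SplineBasisSpec = SplineBasisSpec()

    def __call__(self, f_hz) -> np.ndarray:
        B = build_spline_basis(f_hz, self.basis).to_numpy()
        return self.const + B @ np.asarray(self.coefs)


def flat_shape() -> SplineShape:
    return SplineShape(const=0.0, coefs=(0.0,) * SplineBasisSpec().n_columns)


def default_double_bump_shape() -> SplineShape:
    """The 'double bump' mean frequency profile: thresholds climb steeply
    from 500 to 3000 Hz, dip in the 4000-5000 Hz region, then rise to a
    dome with its peak near 10000 Hz, with an overall base-over-apex trend.

    The coefficients are the (unique) cubic spline with knots at 5000 and
    10000 Hz satisfying six deterministic control conditions chosen to
    encode exactly those features: s(500) = -7, s(2800) = +5 with
    s'(2800) = 0 (crest of the initial rise), s(10000) = +8 with
    s'(10000) = 0 (the dome peak), and s(16000) = -1 C.L. to pin the basal
    tail.  The linear solve is done in kHz units for conditioning and
    converted back to the raw-Hz basis.
    """
    spec = SplineBasisSpec()
    k1, k2 = (k / 1000.0 for k in spec.knots)

    def row_val(f):  # basis row [1, f, f^2, f^3, tp1, tp2] in kHz units
        return [1.0, f, f**2, f**3, max(f - k1, 0.0) ** 3, max(f - k2, 0.0) ** 3]

    def row_deriv(f):
        return [0.0, 1.0, 2 * f, 3 * f**2,
                3 * max(f - k1, 0.0) ** 2, 3 * max(f - k2, 0.0) ** 2]

    A = np.array([
        row_val(0.5), row_val(2.8), row_deriv(2.8),
        row_val(10.0), row_deriv(10.0), row_val(16.0),
    ])
    b = np.array([-7.0, 5.0, 0.0, 8.0, 0.0, -1.0])
    sol = np.linalg.solve(A, b)
    # convert kHz-basis coefficients to the raw-Hz basis
    scale = np.array([1.0, 1e-3, 1e-6, 1e-9, 1e-9, 1e-9])
    const, *coefs = sol * scale
    return SplineShape(const=float(const), coefs=tuple(float(c) for c in coefs), basis=spec)


# Calibrated so that a large default cohort reproduces the target grand mean
# and within/between-subject SDs (see calibrate_config); values frozen from
# one calibration run at n_subjects = 2000.
_CALIBRATED_INTERCEPT = 177.66
_CALIBRATED_SIGMA_B = 13.75
_CALIBRATED_SIGMA_E = 13.16


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth for the synthetic cohort.

    Distributions mirror the source cohort's summary statistics: impedance
    8.71 kOhm (between-subject SD 2.05, within 1.60, observed range
    [2.86, 19.07]); cochlear duct length 35.05 +- 4.68 mm in [26.38, 43.42];
    insertion angle 346 +- 22 deg (PMA), 312 +- 46 (SA), 335 +- 35 (SSA);
    35.48% of perimodiolar arrays translocated to the scala vestibuli; array
    mix 27/2/2 and etiology mix 11/8/4/4/3/1 over 31 subjects.
    """

    n_subjects: int = 31
    n_electrodes: int = 22
    seed: int = 0

    # fixed effects (C.L. per covariate unit), adjusted-model defaults
    intercept_cl: float = _CALIBRATED_INTERCEPT
    beta_imp_sq: float = -0.11          # per kOhm^2
    beta_dist_sq: float = 2.20          # per mm^2
    beta_st: float = -8.50              # scala tympani vs scala vestibuli
    array_effects: dict = field(default_factory=lambda: {"PMA": -5.94, "SA": 13.43, "SSA": 0.0})
    etiology_effects: dict = field(default_factory=lambda: {
        "progressive_snhl": 0.0, "viral": 2.55, "genetic": -3.44,
        "autoimmune": -10.50, "ototoxic": -24.33, "otosclerosis": -4.09,
    })
    beta_age_test: float = 0.29         # per yr
    beta_duration: float = -0.17        # per yr
    spline_shape: SplineShape | None = field(default_factory=default_double_bump_shape)

    # variance components (C.L.)
    sigma_b: float = _CALIBRATED_SIGMA_B
    sigma_e: float = _CALIBRATED_SIGMA_E

    # sampling distributions
    impedance_mean: float = 8.71
    impedance_sd_between: float = 2.05
    impedance_sd_within: float = 1.60
    impedance_clip: tuple = (2.86, 19.07)
    insertion_model: dict = field(default_factory=lambda: {
        "PMA": (346.0, 22.0), "SA": (312.0, 46.0), "SSA": (335.0, 35.0),
    })
    # full insertion: most basal contact at least this far inside the round
    # window; floors the insertion-angle draw for small cochleae
    basal_margin_mm: float = 0.5
    cdl_mean: float = 35.05
    cdl_sd: float = 4.68
    cdl_clip: tuple = (26.38, 43.42)
    p_sv_translocation_pma: float = 0.3548
    array_mix: dict = field(default_factory=lambda: {"PMA": 27, "SA": 2, "SSA": 2})
    etiology_mix: dict = field(default_factory=lambda: {
        "progressive_snhl": 11, "genetic": 8, "autoimmune": 4,
        "ototoxic": 4, "otosclerosis": 3, "viral": 1,
    })
    # electrode-modiolus distance (mm): per-array (mean, sd), clipped
    distance_model: dict = field(default_factory=lambda: {
        "PMA": (0.4, 0.2), "SA": (0.8, 0.3), "SSA": (0.8, 0.3),
    })
    distance_clip: tuple = (0.05, 2.0)
    # demographics (yr)
    age_deaf_mean: float = 40.26
    age_deaf_sd: float = 23.20
    age_deaf_clip: tuple = (0.0, 80.0)
    duration_deaf_mean: float = 5.30
    duration_deaf_sd: float = 5.32
    duration_deaf_clip: tuple = (1.0, 30.0)
    followup_mean_yr: float = 2.0

    sg_map: str = "identity"
    quantize: bool = True

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_electrodes < 1:
            raise ValueError("n_subjects and n_electrodes must be positive")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("variance components must be non-negative")
        if not 0.0 <= self.p_sv_translocation_pma <= 1.0:
            raise ValueError("translocation probability must lie in [0, 1]")
        if any(v < 0 for v in self.array_mix.values()):
            raise ValueError("array_mix counts must be non-negative")
        if sum(self.array_mix.values()) != self.n_subjects:
            raise ValueError(
                f"array_mix sums to {sum(self.array_mix.values())}, "
                f"expected n_subjects = {self.n_subjects}; "
                "use with_n_subjects() to rescale"
            )
        unknown = set(self.etiology_mix) - set(ETIOLOGY_LEVELS)
        if unknown:
            raise ValueError(f"unknown etiology levels: {sorted(unknown)}")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        shape = self.spline_shape
        if shape is None:
            d["spline_shape"] = None
        else:
            d["spline_shape"] = {"const": shape.const, "coefs": list(shape.coefs),
                                 "knots": list(shape.basis.knots)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        shape = d.get("spline_shape", "default")
        if shape == "default":
            d["spline_shape"] = default_double_bump_shape()
        elif shape == "flat" :
            d["spline_shape"] = flat_shape()
        elif isinstance(shape, dict):
            basis = SplineBasisSpec(knots=tuple(shape.get("knots", SplineBasisSpec().knots)))
            d["spline_shape"] = SplineShape(
                const=float(shape["const"]),
                coefs=tuple(float(c) for c in shape["coefs"]),
                basis=basis,
            )
        for key in ("impedance_clip", "cdl_clip", "distance_clip",
                    "age_deaf_clip", "duration_deaf_clip"):
            if key in d:
                d[key] = tuple(d[key])
        if "insertion_model" in d:
            d["insertion_model"] = {k: tuple(v) for k, v in d["insertion_model"].items()}
        if "distance_model" in d:
            d["distance_model"] = {k: tuple(v) for k, v in d["distance_model"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown generator-config fields: {sorted(unknown)}")
        return cls(**d)

    def with_n_subjects(self, n: int) -> "GeneratorConfig":
        """Rescale the array and etiology composition to ``n`` subjects,
        keeping the default proportions (largest-remainder rounding)."""
        return self.replace(
            n_subjects=n,
            array_mix=proportional_counts(self.array_mix, n),
            etiology_mix=proportional_counts(self.etiology_mix, n),
        )


def default_config() -> GeneratorConfig:
    return GeneratorConfig()


def proportional_counts(weights: dict, n: int) -> dict:
    """Allocate ``n`` items over categories proportionally to ``weights``
    with largest-remainder rounding (deterministic, insertion-order ties)."""
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("weights must have a positive sum")
    quotas = {k: n * v / total for k, v in weights.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    remainder = n - sum(counts.values())
    order = sorted(weights, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Normal draw clipped to [lo, hi] (moment-matching is not attempted;
    the clip bounds mirror observed data ranges)."""
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def generate_cohort(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    registry=None,
) -> pd.DataFrame:
    """Draw a synthetic cohort table, one row per (subject, electrode).

    Fully reproducible from ``seed`` (falls back to ``config.seed``).
    Geometry-dependent columns (``x_oc_frac``, ``z_sg_frac``, ``cnf_hz``) are
    computed through the geometry module; the insertion-angle draw is
    truncated below at the smallest angle for which the whole contact span
    fits inside the drawn cochlea, so the geometry is always self-consistent.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    registry = registry or geometry.default_array_registry()
    n_s, n_e = config.n_subjects, config.n_electrodes

    # subject-level composition: deterministic counts, randomized pairing
    array_types = np.repeat(
        list(config.array_mix.keys()), list(config.array_mix.values())
    )
    array_types = rng.permutation(array_types)
    etio_counts = proportional_counts(config.etiology_mix, n_s)
    etiologies = rng.permutation(
        np.repeat(list(etio_counts.keys()), list(etio_counts.values()))
    )

    cdl = _truncated_normal(rng, config.cdl_mean, config.cdl_sd, *config.cdl_clip, size=n_s)
    diameter_a = cdl / geometry.cdl_from_diameter(1.0)

    theta = np.empty(n_s)
    for i, at in enumerate(array_types):
        mu, sd = config.insertion_model[at]
        span = registry[at].span_mm
        lo = geometry.min_feasible_insertion_angle(
            diameter_a[i], span + config.basal_margin_mm
        )
        theta[i] = np.clip(rng.normal(mu, sd), lo, geometry.DEFAULT_TOTAL_ANGLE)

    scalar = np.where(
        (array_types == "PMA") & (rng.random(n_s) < config.p_sv_translocation_pma),
        "SV",
        "ST",
    )

    age_deaf = _truncated_normal(
        rng, config.age_deaf_mean, config.age_deaf_sd, *config.age_deaf_clip, size=n_s
    )
    duration = _truncated_normal(
        rng, config.duration_deaf_mean, config.duration_deaf_sd,
        *config.duration_deaf_clip, size=n_s,
    )
    age_implant = age_deaf + duration
    age_test = age_implant + 0.5 + rng.exponential(config.followup_mean_yr, size=n_s)

    imp_shift = rng.normal(0.0, config.impedance_sd_between, size=n_s)
    b_i = rng.normal(0.0, config.sigma_b, size=n_s)

    rows = []
    for i in range(n_s):
        at = array_types[i]
        imp = np.clip(
            config.impedance_mean + imp_shift[i]
            + rng.normal(0.0, config.impedance_sd_within, size=n_e),
            *config.impedance_clip,
        )
        dmu, dsd = config.distance_model[at]
        dist = np.clip(rng.normal(dmu, dsd, size=n_e), *config.distance_clip)
        rows.append(pd.DataFrame({
            "subject_id": f"S{i + 1:04d}",
            "electrode": np.arange(1, n_e + 1),
            "array_type": at,
            "impedance_kohm": imp,
            "distance_mm": dist,
            "scalar": scalar[i],
            "diameter_A_mm": diameter_a[i],
            "insertion_angle_deg": theta[i],
            "age_test_yr": age_test[i],
            "age_deaf_yr": age_deaf[i],
            "duration_deaf_yr": duration[i],
            "age_implant_yr": age_implant[i],
            "etiology": etiologies[i],
        }))
    table = pd.concat(rows, ignore_index=True)

    table = geometry.map_cohort_cnf(table, registry=registry, sg_map=config.sg_map)

    shape = config.spline_shape or flat_shape()
    eta = (
        config.intercept_cl
        + shape(table["cnf_hz"].to_numpy())
        + config.beta_imp_sq * table["impedance_kohm"].to_numpy() ** 2
        + config.beta_dist_sq * table["distance_mm"].to_numpy() ** 2
        + config.beta_st * (table["scalar"].to_numpy() == "ST")
        + np.vectorize(config.array_effects.__getitem__)(table["array_type"].to_numpy())
        + np.vectorize(config.etiology_effects.__getitem__)(table["etiology"].to_numpy())
        + config.beta_age_test * table["age_test_yr"].to_numpy()
        + config.beta_duration * table["duration_deaf_yr"].to_numpy()
        + np.repeat(b_i, n_e)
    )
    y = eta + rng.normal(0.0, config.sigma_e, size=len(table))
    if config.quantize:
        y = np.clip(np.round(y), 0, 255)
    table["nrt_threshold_cl"] = y
    return table


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _within_between(values: np.ndarray, subjects: np.ndarray) -> tuple[float, float]:
    """Pooled within-subject SD (one-way ANOVA residual SD, the repeated-
    measurement SD of Bland & Altman) and between-subject SD (sample SD of
    the subject means)."""
    df = pd.DataFrame({"s": subjects, "y": values})
    g = df.groupby("s")["y"]
    means, sizes = g.mean(), g.size()
    ss_within = float(((df["y"] - means.reindex(df["s"]).to_numpy()) ** 2).sum())
    dof = int((sizes - 1).sum())
    within = np.sqrt(ss_within / dof) if dof > 0 else float("nan")
    between = float(means.std(ddof=1)) if len(means) > 1 else float("nan")
    return float(within), between


def summarize_cohort(table: pd.DataFrame) -> dict:
    """Cohort summary: grand mean, within- and between-subject SD and range
    for NRT threshold and impedance; per-array and overall subject-level
    insertion-angle means; scala-vestibuli fraction among perimodiolar
    subjects.  With a single subject the between-subject SDs are NaN."""
    out: dict = {
        "n_subjects": int(table["subject_id"].nunique()),
        "n_rows": int(len(table)),
    }
    for key, col in [("nrt", "nrt_threshold_cl"), ("impedance", "impedance_kohm")]:
        v = table[col].to_numpy(dtype=float)
        within, between = _within_between(v, table["subject_id"].to_numpy())
        out[key] = {
            "mean": float(v.mean()),
            "sd_within": within,
            "sd_between": between,
            "min": float(v.min()),
            "max": float(v.max()),
        }
    subj = table.drop_duplicates("subject_id")
    out["insertion_angle_deg"] = {
        "mean": float(subj["insertion_angle_deg"].mean()),
        "by_array": subj.groupby("array_type")["insertion_angle_deg"].mean().to_dict(),
    }
    pma = subj[subj["array_type"] == "PMA"]
    out["pma_sv_fraction"] = (
        float((pma["scalar"] == "SV").mean()) if len(pma) else float("nan")
    )
    return out


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_config(
    config: GeneratorConfig | None = None,
    n_subjects: int = 2000,
    seed: int = 20240515,
    target_mean: float = 169.68,
    target_within_sd: float = 13.66,
    target_between_sd: float = 18.60,
) -> GeneratorConfig:
    """Back-solve the intercept and the two variance components so a large
    generated cohort reproduces the target grand mean and within/between
    SDs.

    One noiseless cohort (``sigma_b = sigma_e = 0``, no quantization)
    measures how much of the spread the covariates and the frequency profile
    already explain; the residual spread is then assigned to ``sigma_e`` and
    ``sigma_b`` in quadrature, and the intercept is shifted to centre the
    grand mean.  The shipped default config freezes one such calibration.
    """
    config = config or default_config()
    probe = config.with_n_subjects(n_subjects).replace(
        sigma_b=0.0, sigma_e=0.0, quantize=False
    )
    table = generate_cohort(probe, seed=seed)
    y = table["nrt_threshold_cl"].to_numpy()
    within_expl, between_expl = _within_between(y, table["subject_id"].to_numpy())
    sigma_e = float(np.sqrt(max(target_within_sd**2 - within_expl**2, 0.0)))
    sigma_b = float(np.sqrt(max(target_between_sd**2 - between_expl**2, 0.0)))
    intercept = float(config.intercept_cl + target_mean - y.mean())
    return config.replace(intercept_cl=intercept, sigma_b=sigma_b, sigma_e=sigma_e)
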