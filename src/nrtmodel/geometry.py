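"""Cochlear tonotopic geometry.

Maps CT-derived cochlear measurements (large diameter *A*, electrode-array
insertion angle) and the physical contact layout of an electrode array to a
characteristic auditory-neuron frequency (CNF) per electrode contact.

The chain is:

1. Escudé's arc-length formula gives the cochlear duct length (CDL) from the
   large diameter ``A`` of the basal turn, assuming a cochlea coiled over
   2.75 turns (990 degrees): ``CDL = 2.62 * A * ln(1 + 990/235) = 4.3259 * A``.
2. The arc position of the most apical contact follows from its insertion
   angle through the same arc-length formula; more basal contacts are offset
   by the manufacturer's inter-contact distances.
3. Relative organ-of-Corti position is converted to relative spiral-ganglion
   position (identity by default; see :func:`oc_to_sg`).
4. Greenwood's place-frequency function ``F = 165.4 * (10**(2.1*z) - 0.88)``
   maps spiral-ganglion position (fraction of length measured from the apex)
   to frequency in Hz.

Positions are stored throughout as fractions of CDL measured *from the round
window* (the base).  Greenwood's argument runs from the apex, so the caller
of :func:`greenwood_cf` flips the coordinate: a deeper insertion means a more
apical contact and hence a lower characteristic frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ESCUDE_ANGLE_CONSTANT",
    "DEFAULT_TOTAL_ANGLE",
    "CochleaSpec",
    "ElectrodeArraySpec",
    "ElectrodePlacement",
    "cdl_from_diameter",
    "arc_length",
    "min_feasible_insertion_angle",
    "electrode_arc_positions",
    "oc_to_sg",
    "greenwood_cf",
    "cnf_from_base_fraction",
    "map_cohort_cnf",
    "load_array_registry",
    "default_array_registry",
]

# Escudé arc-length model: s(theta) = 2.62 * A * ln(1 + theta / 235)
ESCUDE_LENGTH_COEF = 2.62
ESCUDE_ANGLE_CONSTANT = 235.0
# A fully coiled human cochlea: 2.75 turns.
DEFAULT_TOTAL_ANGLE = 2.75 * 360.0

# Greenwood place-frequency constants for the human cochlea.
GREENWOOD_A = 165.4
GREENWOOD_ALPHA = 2.1
GREENWOOD_K = 0.88

ARRAY_TYPES = ("PMA", "SA", "SSA")


def arc_length(diameter_a: float, angle_deg) -> np.ndarray | float:
    """Arc length (mm) along the cochlear duct from the round window to the
    point at ``angle_deg`` degrees, per Escudé's spiral model."""
    diameter_a = float(diameter_a)
    if diameter_a <= 0:
        raise ValueError(f"cochlear diameter A must be positive, got {diameter_a}")
    angle = np.asarray(angle_deg, dtype=float)
    if np.any(angle < 0):
        raise ValueError("insertion angle must be non-negative")
    return ESCUDE_LENGTH_COEF * diameter_a * np.log1p(angle / ESCUDE_ANGLE_CONSTANT)


def cdl_from_diameter(diameter_a: float, total_angle: float = DEFAULT_TOTAL_ANGLE) -> float:
    """Cochlear duct length (mm) from the large diameter ``A`` (mm).

    ``CDL = 2.62 * A * ln(1 + total_angle / 235)``; at the default total coil
    angle of 990 degrees the ratio CDL/A equals 4.3259.
    """
    if diameter_a <= 0:
        raise ValueError(f"cochlear diameter A must be positive, got {diameter_a}")
    if total_angle <= 0:
        raise ValueError(f"total coil angle must be positive, got {total_angle}")
    return float(arc_length(diameter_a, total_angle))


def min_feasible_insertion_angle(diameter_a: float, array_span_mm: float) -> float:
    """Smallest apical-contact insertion angle (degrees) for which the whole
    contact span of the array fits inside the cochlea.

    Inverts the arc-length formula at ``arc = array_span_mm``: below this
    angle the most basal contact would sit outside the round window.
    """
    if diameter_a <= 0:
        raise ValueError("cochlear diameter A must be positive")
    if array_span_mm < 0:
        raise ValueError("array span must be non-negative")
    return ESCUDE_ANGLE_CONSTANT * float(
        np.expm1(array_span_mm / (ESCUDE_LENGTH_COEF * diameter_a))
    )


@dataclass(frozen=True)
class CochleaSpec:
    """A subject's cochlear geometry: large diameter ``A`` (mm), total coil
    angle (degrees, default 990) and the derived duct length."""

    diameter_a: float
    total_angle: float = DEFAULT_TOTAL_ANGLE

    def __post_init__(self) -> None:
        if self.diameter_a <= 0:
            raise ValueError("diameter_a must be positive")
        if self.total_angle <= 0:
            raise ValueError("total_angle must be positive")

    @property
    def cdl(self) -> float:
        return cdl_from_diameter(self.diameter_a, self.total_angle)


@dataclass(frozen=True)
class ElectrodeArraySpec:
    """Physical contact layout of an electrode array.

    ``spacings_y[n-1]`` is the arc distance (mm) from electrode 1 (the most
    apical contact) to electrode ``n``; ``spacings_y[0] == 0``.
    """

    array_type: str
    spacings_y: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.array_type not in ARRAY_TYPES:
            raise ValueError(
                f"unknown array type {self.array_type!r}; supported: {ARRAY_TYPES}"
            )
        y = np.asarray(self.spacings_y, dtype=float)
        if y.size < 1 or y[0] != 0.0:
            raise ValueError("spacings_y must start at 0 (electrode 1)")
        if np.any(np.diff(y) <= 0):
            raise ValueError("spacings_y must be strictly increasing")

    @property
    def n_contacts(self) -> int:
        return len(self.spacings_y)

    @property
    def span_mm(self) -> float:
        return float(self.spacings_y[-1])

    @classmethod
    def uniform(cls, array_type: str, span_mm: float, n_contacts: int = 22) -> "ElectrodeArraySpec":
        y = np.linspace(0.0, span_mm, n_contacts)
        return cls(array_type=array_type, spacings_y=tuple(y))


@dataclass(frozen=True)
class ElectrodePlacement:
    """Surgical placement of the array: insertion angle of the most apical
    contact (degrees from the round window), per-contact scalar compartment
    (ST or SV) and per-contact distance to the modiolus (mm)."""

    insertion_angle_e1: float
    scalar_placement: tuple[str, ...] = ()
    modiolus_distance: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.insertion_angle_e1 <= 0:
            raise ValueError("insertion angle must be positive")
        if any(s not in ("ST", "SV") for s in self.scalar_placement):
            raise ValueError("scalar placement entries must be 'ST' or 'SV'")
        if any(d < 0 for d in self.modiolus_distance):
            raise ValueError("modiolus distances must be non-negative")


def electrode_arc_positions(
    cochlea: CochleaSpec,
    array: ElectrodeArraySpec,
    placement: ElectrodePlacement,
) -> np.ndarray:
    """Relative organ-of-Corti position of each contact, as a fraction of CDL
    measured from the round window.

    Electrode 1 (most apical) sits at arc length
    ``2.62 * A * ln(1 + theta_e1 / 235)``; electrode ``n`` is ``Y_n`` mm more
    basal.  The output is strictly decreasing in electrode number.
    """
    theta = placement.insertion_angle_e1
    if theta > cochlea.total_angle:
        raise ValueError(
            f"insertion angle {theta} deg exceeds total coil angle "
            f"{cochlea.total_angle} deg"
        )
    arc_e1 = float(arc_length(cochlea.diameter_a, theta))
    y = np.asarray(array.spacings_y, dtype=float)
    if y.max() > arc_e1 + 1e-9:
        raise ValueError(
            "array extends outside the cochlea basally: contact offset "
            f"{y.max():.2f} mm exceeds the apical-contact arc length "
            f"{arc_e1:.2f} mm (inconsistent measurements)"
        )
    x = (arc_e1 - y) / cochlea.cdl
    return np.clip(x, 0.0, 1.0)


def oc_to_sg(x, variant: str = "identity"):
    """Map relative organ-of-Corti position to relative spiral-ganglion
    position (both fractions of their respective lengths, from the base).

    The spiral ganglion is shorter than the organ of Corti, so the true
    correspondence compresses basal positions.  Two variants are available:

    - ``"identity"`` (default): returns the input unchanged.  The published
      closed-form fit of the OC-to-SG correspondence is not reproducible from
      the constants at hand (see ``"printed"``), so the pipeline defaults to
      the well-defined monotone identity map.
    - ``"printed"``: evaluates ``Z = 100 / (1 + (23/x - x/0.0099 + 0.76)**2)``
      on the percentage scale and rescales to a fraction.  This transcription
      is non-monotone on (0, 1] and is provided for reference only.
    """
    x = np.asarray(x, dtype=float)
    if variant == "identity":
        if np.any((x < 0) | (x > 1)):
            raise ValueError("organ-of-Corti fraction must lie in [0, 1]")
        return x if x.ndim else float(x)
    if variant == "printed":
        if np.any(x <= 0):
            raise ValueError("printed OC->SG map is undefined at x = 0")
        if np.any(x > 1):
            raise ValueError("organ-of-Corti fraction must lie in (0, 1]")
        z_percent = 100.0 / (1.0 + (23.0 / x - x / 0.0099 + 0.76) ** 2)
        z = z_percent / 100.0
        return z if z.ndim else float(z)
    raise ValueError(f"unknown OC->SG variant {variant!r}; use 'identity' or 'printed'")


def greenwood_cf(z):
    """Greenwood characteristic frequency (Hz) at relative spiral-ganglion
    position ``z``, a fraction of length measured **from the apex**.

    ``F = 165.4 * (10**(2.1*z) - 0.88)``: about 19.8 Hz at the apex (z=0) and
    about 20677 Hz at the base (z=1); strictly increasing in z.
    """
    z = np.asarray(z, dtype=float)
    if np.any((z < 0) | (z > 1)):
        raise ValueError("spiral-ganglion fraction must lie in [0, 1]")
    f = GREENWOOD_A * (10.0 ** (GREENWOOD_ALPHA * z) - GREENWOOD_K)
    return f if f.ndim else float(f)


def cnf_from_base_fraction(z_from_base, sg_map: str = "identity"):
    """Characteristic neuron frequency from a from-base spiral-ganglion
    fraction.  Flips the coordinate to Greenwood's from-apex convention."""
    z = np.asarray(oc_to_sg(z_from_base, variant=sg_map), dtype=float)
    return greenwood_cf(1.0 - z)


# ---------------------------------------------------------------------------
# Array geometry registry
# ---------------------------------------------------------------------------

def default_array_registry() -> dict[str, ElectrodeArraySpec]:
    """Contact layouts for the supported array families, read from the
    packaged ``arrays.yaml``.

    The shipped spacings are documented placeholders (uniform spacing over a
    nominal contact span); true manufacturer layouts can be supplied with
    :func:`load_array_registry`.
    """
    with resources.files("nrtmodel").joinpath("arrays.yaml").open("r") as fh:
        return _registry_from_mapping(yaml.safe_load(fh))


def _registry_from_mapping(raw: Mapping) -> dict[str, ElectrodeArraySpec]:
    registry: dict[str, ElectrodeArraySpec] = {}
    for name, entry in raw.items():
        if "spacings_mm" in entry:
            registry[name] = ElectrodeArraySpec(
                array_type=name, spacings_y=tuple(float(v) for v in entry["spacings_mm"])
            )
        else:
            registry[name] = ElectrodeArraySpec.uniform(
                name, float(entry["span_mm"]), int(entry.get("n_contacts", 22))
            )
    return registry


def load_array_registry(path: str) -> dict[str, ElectrodeArraySpec]:
    """Load an array-geometry registry from a YAML file.

    Each top-level key is an array type; an entry carries either an explicit
    ``spacings_mm`` list (arc offsets from the apical contact, starting at 0)
    or a ``span_mm`` plus optional ``n_contacts`` for uniform spacing.
    """
    with open(path) as fh:
        return _registry_from_mapping(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Cohort-level mapping
# ---------------------------------------------------------------------------

_GEOMETRY_INPUT_COLS = ("subject_id", "array_type", "diameter_A_mm", "insertion_angle_deg", "electrode")
CNF_COLUMNS = ("x_oc_frac", "z_sg_frac", "cnf_hz")


def map_cohort_cnf(
    table: pd.DataFrame,
    registry: Mapping[str, ElectrodeArraySpec] | None = None,
    sg_map: str = "identity",
) -> pd.DataFrame:
    """Append per-electrode position and characteristic-frequency columns to
    a long-format cohort table.

    Requires columns ``subject_id, array_type, diameter_A_mm,
    insertion_angle_deg, electrode``; uses a ``spacing_Y_mm`` column when
    present, otherwise looks contact offsets up in the array registry.
    Appends ``x_oc_frac`` (from-base organ-of-Corti fraction), ``z_sg_frac``
    (from-base spiral-ganglion fraction) and ``cnf_hz``.  Deterministic and
    idempotent: existing output columns are recomputed.
    """
    missing = [c for c in _GEOMETRY_INPUT_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing geometry columns: {missing}")
    if registry is None:
        registry = default_array_registry()

    out = table.copy()
    x = np.empty(len(out))
    for (sid, atype), idx in out.groupby(["subject_id", "array_type"], sort=False).groups.items():
        rows = out.loc[idx]
        if atype not in registry:
            raise ValueError(
                f"unknown array_type {atype!r} for subject {sid}; "
                f"supported: {sorted(registry)}"
            )
        if "spacing_Y_mm" in rows.columns and rows["spacing_Y_mm"].notna().all():
            y = rows["spacing_Y_mm"].to_numpy(dtype=float)
        else:
            spec = registry[atype]
            y = np.asarray(spec.spacings_y)[rows["electrode"].to_numpy(dtype=int) - 1]
        a = float(rows["diameter_A_mm"].iloc[0])
        theta = float(rows["insertion_angle_deg"].iloc[0])
        arc_e1 = float(arc_length(a, theta))
        if y.max() > arc_e1 + 1e-9:
            raise ValueError(
                f"subject {sid}: array extends outside the cochlea basally "
                f"(offset {y.max():.2f} mm > arc {arc_e1:.2f} mm)"
            )
        x[out.index.get_indexer(idx)] = np.clip((arc_e1 - y) / cdl_from_diameter(a), 0.0, 1.0)

    z = np.asarray(oc_to_sg(x, variant=sg_map), dtype=float)
    out["x_oc_frac"] = x
    out["z_sg_frac"] = z
    out["cnf_hz"] = greenwood_cf(1.0 - z)
    return out
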