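"""Domain types and I/O for the substrate-cultivation experiment.

The experimental design is a 4-component compositional substrate — beech
sawdust (BS), hornbeam sawdust (HS), wheat bran (WB) and rice bran (RB),
percentages by dry mass summing to 100 — grown in 825 g bags at 70% initial
moisture, with seven recorded responses per bag:

========  =========================================  =========
name      meaning                                    units
========  =========================================  =========
SRP       spawn run period                           days
DPHF      days to pinhead formation                  days
DFFH      days to first harvest                      days
NFB       number of fruiting bodies                  count/bag
YIELD     fresh fruiting-body mass                   g/bag
BE        biological efficiency                      %
TCP       total cultivation period                   days
========  =========================================  =========

NFB is carried as data but excluded from modelling; the six remaining
responses are the modelled outputs. The 16-formulation summary table
(mean ± SE over 12 replicate bags) ships with the package as an embedded
CSV fixture.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError, DomainError, SchemaError

#: Input (composition) columns, canonical order.
COMPONENTS = ("bs_pct", "hs_pct", "wb_pct", "rb_pct")

#: Nominal wet substrate mass per bag (g) and its initial moisture fraction.
BAG_WET_MASS_G = 825.0
BAG_MOISTURE_FRACTION = 0.70
#: Nominal dry substrate mass per bag: 825 g × (1 − 0.70).
BAG_DRY_MASS_G = BAG_WET_MASS_G * (1.0 - BAG_MOISTURE_FRACTION)

_COMP_SUM_TOL = 1e-9


class Response(enum.Enum):
    """The seven recorded responses: (column, units, optimization direction)."""

    SRP = ("srp_days", "days", "min")
    DPHF = ("dphf_days", "days", "min")
    DFFH = ("dffh_days", "days", "min")
    NFB = ("nfb_count", "count/bag", "max")
    YIELD = ("yield_g", "g/bag", "max")
    BE = ("be_pct", "%", "max")
    TCP = ("tcp_days", "days", "min")

    def __init__(self, column: str, units: str, direction: str):
        self.column = column
        self.units = units
        self.direction = direction

    @property
    def prefix(self) -> str:
        """Column prefix used in summary tables (``<prefix>_mean``/``_se``)."""
        return self.column.rsplit("_", 1)[0]


#: The six modelled responses (all but NFB), in reporting order.
MODELED_RESPONSES = (
    Response.YIELD,
    Response.BE,
    Response.SRP,
    Response.DPHF,
    Response.DFFH,
    Response.TCP,
)

#: Period responses whose within-record ordering must hold:
#: SRP ≤ DPHF ≤ DFFH ≤ TCP.
PERIOD_ORDER = (Response.SRP, Response.DPHF, Response.DFFH, Response.TCP)

REPLICATE_COLUMNS = (
    "label",
    *COMPONENTS,
    "replicate_id",
    "srp_days",
    "dphf_days",
    "dffh_days",
    "yield_g",
    "be_pct",
    "tcp_days",
)
OPTIONAL_REPLICATE_COLUMNS = ("nfb_count",)

SUMMARY_COLUMNS = (
    "label",
    *COMPONENTS,
    "cn_ratio",
    "n",
    *[f"{r.prefix}_{stat}" for r in Response for stat in ("mean", "se")],
)


def resolve_response(response: "Response | str") -> Response:
    """Accept a :class:`Response`, its name (``"YIELD"``) or column (``"yield_g"``)."""
    if isinstance(response, Response):
        return response
    key = str(response).upper()
    if key in Response.__members__:
        return Response[key]
    for r in Response:
        if r.column == str(response):
            return r
    raise DomainError(f"unknown response {response!r}")


@dataclass(frozen=True)
class SubstrateMix:
    """A compositional substrate formulation (percent by dry mass, sums to 100)."""

    label: str
    bs_pct: float
    hs_pct: float
    wb_pct: float
    rb_pct: float

    def __post_init__(self):
        comp = self.composition
        if not np.all(np.isfinite(comp)):
            raise DataValidationError(f"{self.label}: non-finite composition {comp}")
        if np.any(comp < 0):
            raise DataValidationError(f"{self.label}: negative component in {comp}")
        total = float(comp.sum())
        if not math.isclose(total, 100.0, rel_tol=0.0, abs_tol=_COMP_SUM_TOL):
            raise DataValidationError(
                f"{self.label}: components sum to {total}, expected 100"
            )

    @property
    def composition(self) -> np.ndarray:
        return np.array(
            [self.bs_pct, self.hs_pct, self.wb_pct, self.rb_pct], dtype=float
        )


@dataclass
class Dataset:
    """Replicate-level observations plus the provenance that produced them.

    ``frame`` uses the canonical replicate schema (:data:`REPLICATE_COLUMNS`,
    optionally ``nfb_count``); ``provenance`` records either generator
    parameters and seed or the source file path.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """Composition matrix, records × 4, canonical column order."""
        return self.frame.loc[:, list(COMPONENTS)].to_numpy(dtype=float)

    def y(self, response: "Response | str") -> np.ndarray:
        return self.frame[resolve_response(response).column].to_numpy(dtype=float)


def biological_efficiency(
    fresh_yield,
    substrate_wet_mass: float = BAG_WET_MASS_G,
    moisture_fraction: float = BAG_MOISTURE_FRACTION,
):
    """Biological efficiency (%): fresh fruiting-body mass over dry substrate mass.

    BE = 100 × fresh_yield / (substrate_wet_mass × (1 − moisture_fraction)).
    With the nominal 825 g bags at 70% moisture the denominator is 247.5 g dry
    substrate. Accepts scalars or arrays for ``fresh_yield``; full precision is
    kept (round only at report time).
    """
    fy = np.asarray(fresh_yield, dtype=float)
    if not np.all(np.isfinite(fy)) or np.any(fy < 0):
        raise DomainError("fresh_yield must be finite and non-negative")
    if not np.isfinite(substrate_wet_mass) or substrate_wet_mass <= 0:
        raise DomainError("substrate_wet_mass must be positive and finite")
    if not np.isfinite(moisture_fraction) or not 0.0 <= moisture_fraction < 1.0:
        raise DomainError(
            "moisture_fraction must lie in [0, 1); at 1 the dry mass is zero"
        )
    be = 100.0 * fy / (substrate_wet_mass * (1.0 - moisture_fraction))
    return float(be) if np.isscalar(fresh_yield) else be


def load_substrate_summary() -> pd.DataFrame:
    """Load the embedded 16-formulation summary fixture (mean ± SE, n = 12).

    Returns a DataFrame in the canonical summary schema: composition columns,
    carbon-to-nitrogen ratio, replicate count ``n`` and ``<response>_mean`` /
    ``<response>_se`` for the seven responses.
    """
    with resources.files("fungicast.data").joinpath("substrate_summary.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh)
    _validate_summary(df)
    return df


def _validate_summary(df: pd.DataFrame) -> None:
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"summary table missing columns: {missing}")
    _check_compositions(df)
    if (df["n"] < 2).any():
        raise DataValidationError("summary rows must have n >= 2")
    se_cols = [c for c in df.columns if c.endswith("_se")]
    if (df[se_cols] < 0).any().any():
        raise DataValidationError("standard errors must be non-negative")
    mean_cols = [f"{r.prefix}_mean" for r in Response]
    if (df[mean_cols] <= 0).any().any():
        raise DataValidationError("positive-valued response means must be > 0")


def _check_compositions(df: pd.DataFrame) -> None:
    comp = df.loc[:, list(COMPONENTS)].to_numpy(dtype=float)
    if np.any(comp < 0):
        bad = np.where((comp < 0).any(axis=1))[0].tolist()
        raise DataValidationError(f"negative composition components at rows {bad}")
    sums = comp.sum(axis=1)
    off = np.where(np.abs(sums - 100.0) > _COMP_SUM_TOL)[0]
    if off.size:
        detail = {int(i): float(sums[i]) for i in off}
        raise DataValidationError(
            f"compositions must sum to 100; offending rows (index: sum): {detail}"
        )


def validate_replicates(
    df: pd.DataFrame, *, check_ordering: bool = True
) -> pd.DataFrame:
    """Validate a replicate-schema frame; returns it with canonical column order."""
    missing = [c for c in REPLICATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"replicate table missing columns: {missing}")
    extra = [
        c
        for c in df.columns
        if c not in REPLICATE_COLUMNS and c not in OPTIONAL_REPLICATE_COLUMNS
    ]
    if extra:
        raise SchemaError(f"replicate table has unknown columns: {extra}")
    _check_compositions(df)

    value_cols = [r.column for r in Response if r.column in df.columns]
    vals = df.loc[:, value_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataValidationError("replicate values must be finite")
    if np.any(vals <= 0):
        bad = np.where((vals <= 0).any(axis=1))[0].tolist()
        raise DataValidationError(f"non-positive response values at rows {bad}")

    # every label must map to one composition
    grouped = df.groupby("label")[list(COMPONENTS)].nunique()
    inconsistent = grouped[(grouped > 1).any(axis=1)].index.tolist()
    if inconsistent:
        raise DataValidationError(
            f"labels with inconsistent compositions: {inconsistent}"
        )

    if check_ordering:
        srp, dphf, dffh, tcp = (df[r.column].to_numpy(float) for r in PERIOD_ORDER)
        ok = (srp <= dphf) & (dphf <= dffh) & (dffh <= tcp)
        if not ok.all():
            bad = np.where(~ok)[0].tolist()
            raise DataValidationError(
                f"period ordering SRP<=DPHF<=DFFH<=TCP violated at rows {bad}"
            )

    cols = [c for c in (*REPLICATE_COLUMNS, *OPTIONAL_REPLICATE_COLUMNS) if c in df.columns]
    return df.loc[:, cols]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".provenance.json")


def write_dataset(dataset: Dataset, path, *, check_ordering: bool = True) -> Path:
    """Write a dataset to CSV (canonical column order) plus a JSON provenance sidecar."""
    path = Path(path)
    frame = validate_replicates(dataset.frame, check_ordering=check_ordering)
    frame.to_csv(path, index=False)
    _sidecar_path(path).write_text(
        json.dumps(dataset.provenance, indent=2, sort_keys=True, default=str),
        encoding="utf-8",
    )
    return path


def read_dataset(path, *, check_ordering: bool = True) -> Dataset:
    """Read a replicate CSV (and its provenance sidecar, if present)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = validate_replicates(pd.read_csv(path), check_ordering=check_ordering)
    sidecar = _sidecar_path(path)
    provenance = (
        json.loads(sidecar.read_text(encoding="utf-8"))
        if sidecar.exists()
        else {"source": str(path)}
    )
    return Dataset(frame=frame, provenance=provenance)
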