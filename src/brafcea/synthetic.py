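"""Synthetic inputs: simulated survival cohorts, KM fixtures, and configs.

Everything the pipeline consumes can be generated here without external
downloads: right-censored cohorts drawn from known Weibull/Gompertz laws (for
parameter-recovery testing of the curve-fitting stage), Kaplan-Meier curves
with numbers-at-risk tables built from those cohorts, a bundled age/sex life
table, and the base-case parameter/cost config fixtures.

The bundled life table is a **synthetic stand-in** for published US all-cause
life tables: annual death probabilities follow a Gompertz-Makeham law
``q(age) = A + B * exp(C * age)`` with sex-specific constants chosen to track
US all-cause mortality at ages 30-90 to within a few percent.  Swap in a real
table via the life-table config path if higher fidelity is needed.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .config import data_path
from .survival import (
    ExponentialLaw,
    GompertzLaw,
    HazardRatioAdjusted,
    KMCurve,
    PseudoIPD,
    SurvivalLaw,
    WeibullLaw,
)

__all__ = [
    "SimCohortSpec",
    "simulate_cohort",
    "cohort_to_km",
    "generate_life_table",
    "make_fixtures",
]

# Gompertz-Makeham annual mortality q(age) = A + B * exp(C * age)
_GM_MALE = (0.0008, 9.1e-5, 0.0811)
_GM_FEMALE = (0.0005, 2.58e-5, 0.0929)
_LIFE_TABLE_AGES = (26, 100)


@dataclass(frozen=True)
class SimCohortSpec:
    """A simulated right-censored cohort: generating law, censoring, seed."""

    n_patients: int
    law: SurvivalLaw
    censor_low: float = 0.0
    censor_high: float = 0.0
    seed: int = 0
    admin_censor: float | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.censor_high < self.censor_low:
            raise ValueError("censoring interval must have low <= high")


def _inverse_transform(law: SurvivalLaw, u: np.ndarray) -> np.ndarray:
    """Event times with S(T) = u, i.e. cumulative hazard -log(u)."""
    x = -np.log(u)  # cumulative hazard draws
    if isinstance(law, HazardRatioAdjusted):
        return _inverse_transform(law.base, np.exp(-x / law.hr))
    if isinstance(law, WeibullLaw):
        return (x / law.lam) ** (1.0 / law.kappa)
    if isinstance(law, ExponentialLaw):
        return x / law.lam
    if isinstance(law, GompertzLaw):
        if abs(law.gamma) < 1e-12:
            return x / law.lam
        arg = 1.0 + law.gamma * x / law.lam
        out = np.full_like(x, np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / law.gamma
        return out
    raise TypeError(f"unsupported law {type(law).__name__}")


def simulate_cohort(spec: SimCohortSpec) -> PseudoIPD:
    """Draw a right-censored cohort from the generating law.

    Event times come from inverse-transform sampling; censor times are
    uniform on (censor_low, censor_high) when the interval is non-empty.
    Laws with a survival plateau (negative-shape Gompertz) produce patients
    who never progress; these require censoring or ``admin_censor`` to yield
    finite records.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n_patients)
    t_event = _inverse_transform(spec.law, u)

    t_cens = np.full(spec.n_patients, np.inf)
    if spec.censor_high > spec.censor_low:
        t_cens = rng.uniform(spec.censor_low, spec.censor_high, size=spec.n_patients)
    if spec.admin_censor is not None:
        t_cens = np.minimum(t_cens, spec.admin_censor)

    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if np.any(~np.isfinite(time)):
        raise ValueError(
            "infinite event times (survival plateau) with no censoring; "
            "set censoring or admin_censor"
        )
    time = np.maximum(time, 1e-12)
    return PseudoIPD(
        time=time,
        event=event,
        meta={"seed": spec.seed, "law": repr(spec.law), "n": spec.n_patients},
    )


def cohort_to_km(ipd: PseudoIPD, risk_table_times) -> KMCurve:
    """Product-limit estimate of a cohort plus numbers at risk at given times."""
    if len(ipd) == 0:
        raise ValueError("cohort is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    risk_times = np.asarray(risk_table_times, dtype=float)
    n_at_risk = np.array([(ipd.time >= t).sum() for t in risk_times], dtype=int)
    return KMCurve(times=times, surv=surv, risk_times=risk_times, n_at_risk=n_at_risk)


def generate_life_table() -> pd.DataFrame:
    """Synthetic US-style all-cause life table (annual q by age and sex)."""
    ages = np.arange(_LIFE_TABLE_AGES[0], _LIFE_TABLE_AGES[1] + 1)
    rows = []
    for age in ages:
        qm = min(_GM_MALE[0] + _GM_MALE[1] * np.exp(_GM_MALE[2] * age), 1.0)
        qf = min(_GM_FEMALE[0] + _GM_FEMALE[1] * np.exp(_GM_FEMALE[2] * age), 1.0)
        rows.append({"age": int(age), "male": round(qm, 6), "female": round(qf, 6)})
    return pd.DataFrame(rows)


_LIFE_TABLE_HEADER = (
    "# Synthetic all-cause life table (annual death probability by age, sex).\n"
    "# Gompertz-Makeham stand-in for published US life tables; see module docs.\n"
)


def write_life_table(path: Path) -> None:
    table = generate_life_table()
    with open(path, "w") as fh:
        fh.write(_LIFE_TABLE_HEADER)
        table.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def make_fixtures(target_dir: str | Path) -> dict[str, Path]:
    """Write the full config fixture set into ``target_dir``.

    Emits the base-case clinical parameter config, the cost config, the
    placeholder adverse-event cost config, and the synthetic life table.
    Output is deterministic: regenerating produces byte-identical files.
    """
    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name in ("parameters.yaml", "costs.yaml", "ae_costs.yaml"):
        dest = target / name
        shutil.copyfile(data_path(name), dest)
        out[name] = dest
    lt = target / "life_table.csv"
    write_life_table(lt)
    out["life_table.csv"] = lt
    return out
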