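"""EBPR cycle stoichiometry and the PAO/GAO two-component mixing model.

In an anaerobic-feast / aerobic-famine cycle, both polyphosphate- and
glycogen-accumulating organisms (PAOs, GAOs) take up volatile fatty acids
(VFAs) anaerobically and store them as polyhydroxyalkanoates (PHA), but only
PAOs release phosphate while doing so.  The molar transformation ratios over
the anaerobic phase — P released, glycogen consumed and PHB/PHV formed per
C-mol of VFA taken up — therefore sit between the pure-PAO and pure-GAO
literature values, and the observed P/VFA ratio linearly interpolates the
PAO fraction of the PAO+GAO biomass:

    f_PAO = (P/VFA_obs - P/VFA_GAO) / (P/VFA_PAO - P/VFA_GAO)

All concentrations are molar: C-mmol/L for carbon species (per carbon atom)
and P-mmol/L for ortho-phosphate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CYCLE_COLUMNS",
    "RatioSet",
    "ReferenceStoichiometry",
    "MixingEstimate",
    "PAO_REFERENCE",
    "GAO_REFERENCE",
    "SBR_OBSERVED",
    "to_cmol",
    "transformation_ratios",
    "pao_fraction",
    "betweenness_check",
    "read_cycle_csv",
    "NoAnaerobicUptakeError",
]

#: cycle time-series schema (CSV header)
CYCLE_COLUMNS = [
    "time_min",
    "phase",
    "hac_cmmol",
    "hpr_cmmol",
    "po4_pmmol",
    "gly_cmmol",
    "phb_cmmol",
    "phv_cmmol",
]

#: (carbon atoms per molecule, molar mass g/mol); ortho-P converts per P atom
COMPOUND_REGISTRY: dict[str, tuple[int | None, float]] = {
    "acetate": (2, 60.052),
    "propionate": (3, 74.079),
    "glucose-monomer": (6, 162.141),  # anhydroglucose unit of glycogen
    "phb-monomer": (4, 86.090),
    "phv-monomer": (5, 100.117),
    "ortho-p": (None, 30.974),
}

RATIO_NAMES = ("p_vfa", "gly_vfa", "pha_vfa", "phb_vfa", "phv_vfa")


class NoAnaerobicUptakeError(ValueError):
    """The anaerobic phase shows no net VFA uptake."""


def to_cmol(mg_per_l: float, compound: str) -> float:
    """Convert a mass concentration (mg/L) to C-mmol/L (P-mmol/L for
    ortho-phosphate)."""
    key = compound.lower()
    if key not in COMPOUND_REGISTRY:
        raise KeyError(f"unknown compound {compound!r}; known: {sorted(COMPOUND_REGISTRY)}")
    carbons, molar_mass = COMPOUND_REGISTRY[key]
    if carbons is None:
        return mg_per_l / molar_mass
    return mg_per_l * carbons / molar_mass


@dataclass(frozen=True)
class RatioSet:
    """Anaerobic transformation ratios relative to VFA uptake (C-mol basis;
    P/VFA in P-mol/C-mol)."""

    p_vfa: float
    gly_vfa: float
    pha_vfa: float
    phb_vfa: float
    phv_vfa: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATIO_NAMES}


@dataclass(frozen=True)
class ReferenceStoichiometry:
    """Literature anaerobic stoichiometry of an enrichment (PAO or GAO)."""

    role: str
    p_vfa: float
    gly_vfa: float
    pha_vfa: float
    phb_vfa: float
    phv_vfa: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATIO_NAMES}


#: acetate-fed model enrichments (literature reference rows)
PAO_REFERENCE = ReferenceStoichiometry("PAO", 0.5, 0.5, 1.33, 1.33, 0.0)
GAO_REFERENCE = ReferenceStoichiometry("GAO", 0.0, 1.12, 1.85, 1.36, 0.46)

#: measured lab-scale SBR ratios of the mixed PAO/GAO enrichment studied
#: alongside the references above (example observation set)
SBR_OBSERVED = RatioSet(0.3, 0.59, 1.72, 1.16, 0.56)


def read_cycle_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in CYCLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cycle CSV missing columns: {missing}")
    return frame


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def transformation_ratios(
    series: pd.DataFrame,
    method: str = "endpoint",
    rate_window_min: float = 30.0,
) -> RatioSet:
    """Anaerobic-phase transformation ratios.

    ``endpoint`` (default) uses the first and last anaerobic samples;
    ``rate`` uses least-squares slopes over the first ``rate_window_min``
    minutes of the anaerobic phase and takes ratios of rates.
    """
    ana = series[series["phase"] == "anaerobic"]
    if len(ana) < 2:
        raise ValueError("series lacks a usable anaerobic phase (need >= 2 samples)")
    vfa = ana["hac_cmmol"].to_numpy(float) + ana["hpr_cmmol"].to_numpy(float)
    po4 = ana["po4_pmmol"].to_numpy(float)
    gly = ana["gly_cmmol"].to_numpy(float)
    phb = ana["phb_cmmol"].to_numpy(float)
    phv = ana["phv_cmmol"].to_numpy(float)
    if method == "endpoint":
        d_vfa = vfa[0] - vfa[-1]
        if d_vfa <= 0:
            raise NoAnaerobicUptakeError("no anaerobic uptake: VFA did not decrease")
        p_rel = po4[-1] - po4[0]
        gly_cons = gly[0] - gly[-1]
        phb_form = phb[-1] - phb[0]
        phv_form = phv[-1] - phv[0]
    elif method == "rate":
        t = ana["time_min"].to_numpy(float)
        window = t <= t[0] + rate_window_min
        if window.sum() < 2:
            raise ValueError("rate window contains fewer than 2 samples")
        tw = t[window]
        d_vfa = -_slope(tw, vfa[window])
        if d_vfa <= 0:
            raise NoAnaerobicUptakeError("no anaerobic uptake: VFA rate not negative")
        p_rel = _slope(tw, po4[window])
        gly_cons = -_slope(tw, gly[window])
        phb_form = _slope(tw, phb[window])
        phv_form = _slope(tw, phv[window])
    else:
        raise ValueError(f"unknown method {method!r}")
    return RatioSet(
        p_vfa=p_rel / d_vfa,
        gly_vfa=gly_cons / d_vfa,
        pha_vfa=(phb_form + phv_form) / d_vfa,
        phb_vfa=phb_form / d_vfa,
        phv_vfa=phv_form / d_vfa,
    )


@dataclass
class MixingEstimate:
    """PAO fraction of the PAO+GAO biomass, with diagnostics."""

    f_pao: float
    f_unclipped: float
    basis: str
    clipped: bool
    warning: str | None = None
    residuals: dict[str, float] = field(default_factory=dict)

    @property
    def f_gao(self) -> float:
        return 1.0 - self.f_pao


DEFAULT_LSQ_RATIOS = ("p_vfa", "gly_vfa", "phb_vfa", "phv_vfa")


def pao_fraction(
    observed: RatioSet,
    pao_ref: ReferenceStoichiometry = PAO_REFERENCE,
    gao_ref: ReferenceStoichiometry = GAO_REFERENCE,
    basis: str = "p_vfa",
    ratios: Sequence[str] = DEFAULT_LSQ_RATIOS,
) -> MixingEstimate:
    """Estimate the PAO fraction by linear two-component mixing.

    ``p_vfa`` basis inverts the P/VFA interpolation directly;
    ``least_squares`` minimizes the squared residuals of the selected ratios
    against ``f * PAO + (1-f) * GAO`` (closed form) and reports per-ratio
    residuals.  Estimates are clipped to [0, 1] with a warning.
    """
    obs = observed.as_dict()
    pao = pao_ref.as_dict()
    gao = gao_ref.as_dict()
    if basis == "p_vfa":
        denom = pao["p_vfa"] - gao["p_vfa"]
        if denom == 0:
            raise ValueError("PAO and GAO references share the same P/VFA; basis unusable")
        f_raw = (obs["p_vfa"] - gao["p_vfa"]) / denom
    elif basis == "least_squares":
        x = np.array([pao[r] - gao[r] for r in ratios])
        y = np.array([obs[r] - gao[r] for r in ratios])
        sxx = float(x @ x)
        if sxx == 0:
            raise ValueError("references identical on all selected ratios")
        f_raw = float(x @ y) / sxx
    else:
        raise ValueError(f"unknown basis {basis!r}")
    clipped = not (0.0 <= f_raw <= 1.0)
    f = min(1.0, max(0.0, f_raw))
    warning = (
        f"estimate {f_raw:.3f} outside [0, 1]; clipped to {f:.1f}" if clipped else None
    )
    residuals = {
        r: obs[r] - (f * pao[r] + (1.0 - f) * gao[r]) for r in ratios
    }
    return MixingEstimate(f, f_raw, basis, clipped, warning, residuals)


def betweenness_check(
    observed: RatioSet,
    pao_ref: ReferenceStoichiometry = PAO_REFERENCE,
    gao_ref: ReferenceStoichiometry = GAO_REFERENCE,
) -> dict[str, str]:
    """For each ratio, report whether the observation lies inside the closed
    interval spanned by the two references ('inside' | 'below' | 'above')."""
    obs = observed.as_dict()
    pao = pao_ref.as_dict()
    gao = gao_ref.as_dict()
    out = {}
    for name in RATIO_NAMES:
        lo, hi = sorted((pao[name], gao[name]))
        if obs[name] < lo:
            out[name] = "below"
        elif obs[name] > hi:
            out[name] = "above"
        else:
            out[name] = "inside"
    return out
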