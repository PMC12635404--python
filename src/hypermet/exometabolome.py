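"""DSS-referenced quantification of culture-medium metabolites.

Spent-medium samples taken at every feed (every 2 days across a 21-day
expansion) are mixed 500 uL + 100 uL with a phosphate buffer containing
0.644 mM DSS.  A metabolite's concentration in the NMR tube follows from
the ratio of its per-proton peak integral to the per-proton DSS integral
(DSS: 9 equivalent trimethylsilyl protons); dividing by the 5/6 sample
dilution gives the concentration in the original supernatant, the frame
in which spent vs fresh medium is compared.

Consumption of a metabolite over a 2-day feed interval is fresh - spent;
a negative value means net production (lactate, pyruvate, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "QuantReference",
    "MetaboliteQuant",
    "ConsumptionProfile",
    "quantify",
    "consumption",
    "population_increase_factor",
    "quantify_panel",
    "assemble_timecourse",
    "TimecourseResult",
    "DEFAULT_PROTON_COUNTS",
]


#: protons under the single peak chosen for quantification of each metabolite
#: (e.g. lactate CH3 doublet = 3H, formate CH singlet = 1H); overridable.
DEFAULT_PROTON_COUNTS: dict[str, int] = {
    "glucose": 1,        # alpha-anomeric H1
    "lactate": 3,        # CH3
    "alanine": 3,        # CH3
    "pyruvate": 3,       # CH3
    "formate": 1,        # CH
    "succinate": 4,      # 2x CH2
    "fumarate": 2,       # 2x CH
    "glutamine": 2,      # gamma-CH2
    "glutamax": 2,       # dipeptide gamma-CH2
    "arginine": 2,       # delta-CH2
    "cysteine": 2,       # beta-CH2
    "histidine": 1,      # imidazole H
    "isoleucine": 3,     # delta-CH3
    "leucine": 3,        # one CH3
    "phenylalanine": 5,  # aromatic
    "tyrosine": 2,       # aromatic 2,6
    "valine": 3,         # one CH3
    "ethanol": 3,        # CH3
}


@dataclass(frozen=True)
class QuantReference:
    """Internal-standard bookkeeping for the DSS-spiked buffer."""

    dss_buffer_conc_mM: float = 0.644
    sample_volume_uL: float = 500.0
    buffer_volume_uL: float = 100.0
    dss_protons: int = 9

    def __post_init__(self) -> None:
        if self.dss_buffer_conc_mM <= 0:
            raise ValueError("dss_buffer_conc_mM must be positive")
        if self.sample_volume_uL <= 0 or self.buffer_volume_uL <= 0:
            raise ValueError("volumes must be positive")
        if self.dss_protons < 1:
            raise ValueError("dss_protons must be >= 1")

    @property
    def total_volume_uL(self) -> float:
        return self.sample_volume_uL + self.buffer_volume_uL

    @property
    def dss_tube_conc_mM(self) -> float:
        """DSS concentration in the measured tube after mixing."""
        return self.dss_buffer_conc_mM * self.buffer_volume_uL / self.total_volume_uL

    @property
    def sample_dilution(self) -> float:
        """Fraction of the tube volume that is original sample (5/6 at defaults)."""
        return self.sample_volume_uL / self.total_volume_uL


@dataclass(frozen=True)
class MetaboliteQuant:
    name: str
    integral: float
    n_protons: int
    conc_mM: float  # original (pre-mixing) sample frame

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if self.conc_mM < 0:
            raise ValueError("conc_mM must be >= 0")


def quantify(
    integral: float,
    n_protons: int,
    dss_integral: float,
    ref: QuantReference = QuantReference(),
) -> float:
    """Concentration (mM) in the original sample from a peak integral.

    tube conc = (integral/n_protons) / (dss_integral/dss_protons) * DSS tube conc;
    dividing by the sample dilution maps back to the pre-mixing supernatant.
    Invariant under common rescaling of both integrals.
    """
    if dss_integral <= 0:
        raise ValueError("dss_integral must be positive")
    if n_protons < 1:
        raise ValueError("n_protons must be >= 1")
    per_proton = integral / n_protons
    dss_per_proton = dss_integral / ref.dss_protons
    tube_conc = per_proton / dss_per_proton * ref.dss_tube_conc_mM
    return tube_conc / ref.sample_dilution


class Consumption(NamedTuple):
    consumed_mM: float
    consumed_fraction: float


def consumption(fresh_mM: float, spent_mM: float) -> Consumption:
    """Consumed amount and fraction over one feed interval.

    Negative values flag net production (spent > fresh).
    """
    if fresh_mM <= 0:
        raise ValueError("fresh_mM must be positive for the fraction to be defined")
    consumed = fresh_mM - spent_mM
    return Consumption(consumed, consumed / fresh_mM)


def population_increase_factor(new_count: float, prev_count: float) -> float:
    """(new - previous) / previous cell count, the proliferation metric."""
    if prev_count <= 0:
        raise ValueError("previous count must be positive")
    return (new_count - prev_count) / prev_count


@dataclass(frozen=True)
class ConsumptionProfile:
    """Per-metabolite consumption across the sampled days (replicate mean/SD)."""

    metabolite: str
    days: np.ndarray
    fresh_mM: np.ndarray
    spent_mM: np.ndarray
    fresh_sd: np.ndarray
    spent_sd: np.ndarray
    n_replicates: np.ndarray

    @property
    def consumed_mM(self) -> np.ndarray:
        return self.fresh_mM - self.spent_mM

    @property
    def consumed_fraction(self) -> np.ndarray:
        return self.consumed_mM / self.fresh_mM

    @property
    def produced(self) -> np.ndarray:
        """Boolean per day: net production (spent above fresh)."""
        return self.consumed_mM < 0


@dataclass
class TimecourseResult:
    profiles: dict[str, ConsumptionProfile]
    orphans: pd.DataFrame  # spent samples lacking a same-day fresh partner

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for prof in self.profiles.values():
            for i, day in enumerate(prof.days):
                rows.append(
                    {
                        "metabolite": prof.metabolite,
                        "day": day,
                        "fresh_mM": prof.fresh_mM[i],
                        "fresh_sd": prof.fresh_sd[i],
                        "spent_mM": prof.spent_mM[i],
                        "spent_sd": prof.spent_sd[i],
                        "consumed_mM": prof.consumed_mM[i],
                        "consumed_fraction": prof.consumed_fraction[i],
                        "produced": bool(prof.produced[i]),
                        "n_replicates": int(prof.n_replicates[i]),
                    }
                )
        return pd.DataFrame(rows).sort_values(["metabolite", "day"]).reset_index(drop=True)


_PANEL_COLUMNS = {"day", "sample_type", "metabolite", "integral", "dss_integral", "replicate"}


def quantify_panel(
    panel: pd.DataFrame,
    ref: QuantReference = QuantReference(),
    proton_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Quantify a long-format integral table into concentrations.

    ``panel`` columns: day, sample_type {spent, fresh}, metabolite,
    integral, dss_integral, replicate, and optionally n_protons (otherwise
    looked up in ``proton_counts`` / the built-in defaults).  Returns a
    copy with a ``conc_mM`` column in the original-sample frame.
    """
    missing = _PANEL_COLUMNS - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    bad_type = set(panel["sample_type"].unique()) - {"spent", "fresh"}
    if bad_type:
        raise ValueError(f"unknown sample_type values: {sorted(bad_type)}")
    counts = dict(DEFAULT_PROTON_COUNTS)
    if proton_counts:
        counts.update({k.lower(): v for k, v in proton_counts.items()})
    out = panel.copy()
    if "n_protons" not in out.columns:
        try:
            out["n_protons"] = [counts[m.lower()] for m in out["metabolite"]]
        except KeyError as exc:
            raise KeyError(
                f"no proton count for metabolite {exc.args[0]!r}; pass proton_counts"
            ) from None
    out["conc_mM"] = [
        quantify(row.integral, int(row.n_protons), row.dss_integral, ref)
        for row in out.itertuples()
    ]
    return out


def assemble_timecourse(conc: pd.DataFrame) -> TimecourseResult:
    """Align spent/fresh pairs per metabolite and day into profiles.

    ``conc`` needs columns day, sample_type, metabolite, replicate and
    conc_mM (see :func:`quantify_panel`).  Spent samples without a
    same-day fresh partner are reported in ``orphans``, never imputed.
    Output is order-independent in the input rows.
    """
    required = {"day", "sample_type", "metabolite", "replicate", "conc_mM"}
    missing = required - set(conc.columns)
    if missing:
        raise ValueError(f"concentration table is missing columns: {sorted(missing)}")

    spent = conc[conc["sample_type"] == "spent"]
    fresh = conc[conc["sample_type"] == "fresh"]
    fresh_days = {
        (m, d) for m, d in zip(fresh["metabolite"], fresh["day"])
    }
    orphan_mask = [
        (m, d) not in fresh_days for m, d in zip(spent["metabolite"], spent["day"])
    ]
    orphans = spent[orphan_mask].copy().sort_values(["metabolite", "day", "replicate"]).reset_index(drop=True)
    paired = spent[[not o for o in orphan_mask]]

    profiles: dict[str, ConsumptionProfile] = {}
    for metabolite in sorted(paired["metabolite"].unique()):
        sp = paired[paired["metabolite"] == metabolite]
        fr = fresh[fresh["metabolite"] == metabolite]
        days = np.array(sorted(sp["day"].unique()), dtype=float)
        sp_g = sp.groupby("day")["conc_mM"]
        fr_g = fr.groupby("day")["conc_mM"]
        spent_mean = np.array([sp_g.mean()[d] for d in days])
        spent_sd = np.array([np.nan_to_num(sp_g.std(ddof=1).get(d, 0.0)) for d in days])
        fresh_mean = np.array([fr_g.mean()[d] for d in days])
        fresh_sd = np.array([np.nan_to_num(fr_g.std(ddof=1).get(d, 0.0)) for d in days])
        n_rep = np.array([sp_g.count()[d] for d in days])
        profiles[metabolite] = ConsumptionProfile(
            metabolite, days, fresh_mean, spent_mean, fresh_sd, spent_sd, n_rep
        )
    return TimecourseResult(profiles=profiles, orphans=orphans)
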