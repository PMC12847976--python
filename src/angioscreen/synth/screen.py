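"""Synthetic drug screens with known generating truth.

Emulates the screening layout of a patient-derived-chip campaign: donors x
treatments x replicate chips spread over plates, with plates nested inside
donors (each plate holds one donor's chips, as on the 64-chip graft plates).
Per-chip readouts are multiplicative:

    value = baseline * plate_effect * donor_effect * treatment_multiplier * noise

with lognormal plate/donor random effects and lognormal replicate noise, so
all readouts stay positive and vehicle normalization recovers scripted
multipliers exactly in the noise-free limit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ..types import DESCRIPTOR_NAMES, ParameterError

#: analyte panel measured in the supernatant (13-plex + IL6)
DEFAULT_ANALYTES = (
    "AFP", "CCL2", "CCL3", "CCL4", "CCL20", "CXCL1", "CXCL10",
    "CXCL11", "IL4", "IL8", "IL21", "CXCL12", "TNFa", "IL6",
)

#: plausible per-chip descriptor baselines (pixel units) for direct
#: table-level simulation (no images involved)
DEFAULT_DESCRIPTOR_BASELINES: Mapping[str, float] = {
    "explant_area": 5.0e5,
    "thick_area": 3.0e4,
    "thin_area": 2.0e4,
    "total_area": 5.0e4,
    "thick_density": 0.10,
    "thin_density": 0.07,
    "total_density": 0.17,
    "n_junctions": 120.0,
    "branching_index": 2.4e-3,
    "total_length": 1.2e4,
    "avg_branch_length": 45.0,
    "avg_width": 4.2,
    "thick_total_area_ratio": 0.6,
    "inout_total_ratio": 1.1,
    "inout_thick_ratio": 1.3,
}


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative effect of one treatment on each readout family.

    ``descriptors`` and ``analytes`` map readout name -> multiplier; missing
    names default to 1 (no effect). A multiplier of 0.47 on viability means
    treated chips sit at 47% of vehicle after plate normalization.
    """

    viability: float = 1.0
    descriptors: Mapping[str, float] = field(default_factory=dict)
    analytes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.viability, *self.descriptors.values(), *self.analytes.values()]
        if any(v < 0 for v in vals):
            raise ParameterError("effect multipliers must be >= 0")


VEHICLE = TreatmentEffect()


@dataclass(frozen=True)
class ScreenDesign:
    """Design of a synthetic screen.

    Defaults mirror the screening layout the package targets: every
    treatment gets 2 chips per plate and the vehicle control 6, with 2
    plates per donor (so 4 treated and 12 vehicle chips per donor).
    """

    donors: tuple[str, ...] = ("D1", "D2", "D3", "D4")
    treatments: Mapping[str, TreatmentEffect] = field(
        default_factory=lambda: {"DMSO": VEHICLE}
    )
    control: str = "DMSO"
    plates_per_donor: int = 2
    replicates_per_plate: int = 2
    control_replicates_per_plate: int = 6
    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    analyte_baseline: float = 100.0  # pg/mL scale
    viability_baseline: float = 50_000.0  # raw fluorescence units
    descriptor_baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_BASELINES)
    )
    donor_sd: float = 0.25  # lognormal sigma of donor random effect
    plate_sd: float = 0.10  # lognormal sigma of plate random effect
    replicate_cv: float = 0.10  # lognormal sigma of chip-level noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in self.treatments:
            raise ParameterError("design must include the vehicle-control treatment")
        ctrl = self.treatments[self.control]
        if ctrl.viability != 1.0 or any(
            v != 1.0 for v in (*ctrl.descriptors.values(), *ctrl.analytes.values())
        ):
            raise ParameterError("vehicle control must have all multipliers = 1")
        if self.replicates_per_plate < 1 or self.control_replicates_per_plate < 1:
            raise ParameterError("replicate counts must be >= 1")
        if min(self.donor_sd, self.plate_sd, self.replicate_cv) < 0:
            raise ParameterError("noise scales must be >= 0")


@dataclass
class ScreenDataset:
    """Layout-indexed tables of one (synthetic or real) screen.

    ``layout`` has columns plate/chip/donor/treatment/replicate; the data
    tables are indexed by chip id. ``truth`` holds the generating design and
    sampled random effects when the dataset is synthetic.
    """

    layout: pd.DataFrame
    viability: pd.DataFrame  # columns: chip, value
    analytes: pd.DataFrame  # columns: chip, <analyte...>
    descriptors: pd.DataFrame  # columns: chip, <descriptor...>
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        chips = set(self.layout["chip"])
        for name, tab in (("viability", self.viability),
                          ("analytes", self.analytes),
                          ("descriptors", self.descriptors)):
            missing = set(tab["chip"]) - chips
            if missing:
                raise ParameterError(f"{name} table has chips absent from layout: "
                                     f"{sorted(missing)[:5]}")
        num = self.analytes.drop(columns="chip").to_numpy(dtype=float)
        if (num < 0).any():
            raise ParameterError("analyte concentrations must be >= 0")

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.layout.to_csv(d / "layout.csv", index=False)
        self.viability.to_csv(d / "viability.csv", index=False)
        self.analytes.to_csv(d / "analytes.csv", index=False)
        self.descriptors.to_csv(d / "descriptors.csv", index=False)

    @classmethod
    def load(cls, directory) -> "ScreenDataset":
        d = Path(directory)
        return cls(
            layout=pd.read_csv(d / "layout.csv"),
            viability=pd.read_csv(d / "viability.csv"),
            analytes=pd.read_csv(d / "analytes.csv"),
            descriptors=pd.read_csv(d / "descriptors.csv"),
        )


def generate_screen(design: ScreenDesign) -> ScreenDataset:
    """Simulate a screen under ``design``; deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    names = list(DESCRIPTOR_NAMES)
    d_base = np.array([
        design.descriptor_baselines.get(n, DEFAULT_DESCRIPTOR_BASELINES[n])
        for n in names
    ])

    donor_eff = {d: float(np.exp(rng.normal(0.0, design.donor_sd)))
                 for d in design.donors}
    rows, via_rows, ana_rows, desc_rows = [], [], [], []
    plate_eff: dict[str, float] = {}
    chip_no = 0
    for donor in design.donors:
        for p in range(design.plates_per_donor):
            plate = f"{donor}_P{p + 1}"
            plate_eff[plate] = float(np.exp(rng.normal(0.0, design.plate_sd)))
            for trt, eff in design.treatments.items():
                n_rep = (design.control_replicates_per_plate
                         if trt == design.control else design.replicates_per_plate)
                for rep in range(n_rep):
                    chip_no += 1
                    chip = f"chip{chip_no:04d}"
                    rows.append({"plate": plate, "chip": chip, "donor": donor,
                                 "treatment": trt, "replicate": rep + 1})
                    scale = donor_eff[donor] * plate_eff[plate]

                    def noise(k=1):
                        if design.replicate_cv == 0:
                            return np.ones(k) if k > 1 else 1.0
                        draw = np.exp(rng.normal(0.0, design.replicate_cv, size=k))
                        return draw if k > 1 else float(draw[0])

                    via_rows.append({
                        "chip": chip,
                        "value": design.viability_baseline * scale
                        * eff.viability * noise(),
                    })
                    a_mult = np.array([eff.analytes.get(a, 1.0)
                                       for a in design.analytes])
                    a_vals = (design.analyte_baseline * scale * a_mult
                              * noise(len(design.analytes)))
                    ana_rows.append({"chip": chip,
                                     **dict(zip(design.analytes, a_vals))})
                    d_mult = np.array([eff.descriptors.get(n, 1.0) for n in names])
                    d_vals = d_base * scale * d_mult * noise(len(names))
                    desc_rows.append({"chip": chip, **dict(zip(names, d_vals))})

    return ScreenDataset(
        layout=pd.DataFrame(rows),
        viability=pd.DataFrame(via_rows),
        analytes=pd.DataFrame(ana_rows),
        descriptors=pd.DataFrame(desc_rows),
        truth={"design": design, "donor_effects": donor_eff,
               "plate_effects": plate_eff},
    )
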