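"""Pipeline configuration and the study constants shared across modules.

Every constant that enters the charge-transfer scoring or the classification
rules is surfaced here so that none of them is hard-coded at the point of use:
the synaptic/non-synaptic suprathreshold bounds (2.5x / 0.4x), the reversal
potential screen threshold (+/- 3.4 mV), the single-channel conductance ratio
used by the MTSEA open-probability estimate (0.67), and the reference ligand
concentrations at which relative responses are evaluated (3 uM glycine, 1 mM
synaptic / 0.1 uM non-synaptic glutamate, 1 mM Mg2+).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Tunable thresholds and reference conditions for the analysis pipeline.

    Attributes
    ----------
    seed:
        Master seed for all synthetic-data generation.
    ct_upper, ct_lower:
        Charge-transfer fold bounds; a fold outside ``[ct_lower, ct_upper]``
        is "suprathreshold" and supports a gain (above) or loss (below) call.
    ddvrev_mv:
        Screen threshold on the variant-minus-WT difference of Ba2+-induced
        reversal-potential shifts, in mV.
    gamma_ratio:
        Ratio of single-channel conductance after/before MTSEA modification;
        converts fold potentiation into maximal open probability.
    gly_ref_um, glu_synaptic_um, glu_nonsynaptic_um, mg_ref_um:
        Ligand concentrations (uM) at which relative responses and Mg2+
        inhibition are evaluated for the charge-transfer composites.
    ec50_floor_um:
        Potency floor (uM) for the fold-change regressions; EC50 values below
        30 nM are excluded because trace agonist contamination distorts them.
    high_conf_fold:
        Minimum fold change (in the display convention) for a significant
        assay change to be graded high rather than moderate confidence.
    """

    seed: int = 0
    ct_upper: float = 2.5
    ct_lower: float = 0.4
    ddvrev_mv: float = 3.4
    gamma_ratio: float = 0.67
    gly_ref_um: float = 3.0
    glu_synaptic_um: float = 1000.0
    glu_nonsynaptic_um: float = 0.1
    mg_ref_um: float = 1000.0
    ec50_floor_um: float = 0.03
    high_conf_fold: float = 2.0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("ct_upper", "ct_lower", "ddvrev_mv", "gamma_ratio",
                     "gly_ref_um", "glu_synaptic_um", "glu_nonsynaptic_um",
                     "mg_ref_um", "ec50_floor_um", "high_conf_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ct_lower >= self.ct_upper:
            raise ValueError("ct_lower must be below ct_upper")
        if not 0 < self.gamma_ratio <= 1:
            raise ValueError("gamma_ratio must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data.update(data.pop("extra"))
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def as_dict(self) -> dict:
        data = asdict(self)
        data.update(data.pop("extra"))
        return data


DEFAULT_CONFIG = PipelineConfig()
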