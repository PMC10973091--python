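"""Packaged per-variant assay summary of the M3-helix variant panel.

``load_assay_summary`` returns the tabulated six-assay summary (potencies
with log-space confidence intervals, pH current ratios, surface/total
expression, open probability, weighted deactivation tau, peak current
density and the synaptic/non-synaptic charge-transfer folds) for 48 M3
transmembrane-helix variants across GluN1, GluN2A and GluN2B, together with
the wild-type reference rows.  Cells that could not be measured because
currents were too small carry an ``nd`` status; assays never run carry
``na``.  Variants assayed on both GluN2A and GluN2B backgrounds appear once
per background block.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_assay_summary"]


def load_assay_summary() -> pd.DataFrame:
    """Per-variant assay summary table as a DataFrame."""
    with resources.files("grinvar.data").joinpath("assay_summary.csv").open() as fh:
        return pd.read_csv(fh)
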