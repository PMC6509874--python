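"""The arachidonic-acid (AA) metabolic network in human PMNs.

The AA pathway in polymorphonuclear leukocytes is the package's worked
disease network: PLA2 releases AA from membrane phospholipid, and AA is
metabolized through 5-LOX, 15-LOX and COX-2 branches producing the
inflammatory mediators LTB4, LTA4 and PGE2.  The disease state is the
untreated network; the normal state demands the 1 h cumulative LTB4
production fall below a fraction θ of the disease output.  Eight enzymes
(PLA2, PHGPx, TXAS, CYP4F3, 5-LOX, 15-LOX, LTA4H, 12-LOX) are the candidate
drug targets.

The shipped model file is a SYNTHETIC stand-in: the network topology follows
the canonical pathway structure, but every kinetic constant is illustrative
rather than fitted to measurements, so screening results on it are
demonstrations of the method, not reproductions of any published
parameterization.  Each constant carries a provenance annotation in
``models/aa_pmn_synthetic_provenance.csv``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import NetworkModel, load_model

__all__ = ["AA_TARGETS", "load_aa_model", "load_aa_provenance"]

AA_TARGETS = (
    "PLA2", "PHGPx", "TXAS", "CYP4F3", "5-LOX", "15-LOX", "LTA4H", "12-LOX",
)

_MODEL_FILE = "aa_pmn_synthetic.yaml"
_PROVENANCE_FILE = "aa_pmn_synthetic_provenance.csv"


def _model_path(name: str):
    return resources.files("synscreen") / "models" / name


def load_aa_model() -> NetworkModel:
    """Load and validate the shipped synthetic AA PMN network model."""
    with resources.as_file(_model_path(_MODEL_FILE)) as path:
        return load_model(path)


def load_aa_provenance() -> pd.DataFrame:
    """Per-constant provenance table (reaction, constant, value, provenance)."""
    with resources.as_file(_model_path(_PROVENANCE_FILE)) as path:
        return pd.read_csv(path)
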