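"""Small bundled datasets."""

from importlib import resources

import pandas as pd

__all__ = ["load_validated_ar_clones"]


def load_validated_ar_clones() -> pd.DataFrame:
    """The published panel of 15 antigen-reactive anti-c-Met scFv clones.

    These are the phage clones recovered as antigen-reactive after one
    panning round of the prediction-guided AR library in the chicken
    anti-c-Met campaign; columns are ``clone_id``, ``hcdr3_aa`` and
    ``lcdr3_aa``. Two clones encode the same scFv, and several light
    chains recur across heavy partners, so the panel is the canonical
    worked example for :func:`biopanml.panel.pairing_report`.
    """
    ref = resources.files("biopanml.data").joinpath("validated_ar_clones.tsv")
    with ref.open("r") as handle:
        return pd.read_csv(handle, sep="\t")
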