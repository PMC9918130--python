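"""Classification of gene dynamics across the C -> A20 -> AD timeline.

Each gene's three pairwise contrast results (C_A20, C_AD, A20_AD) are
reduced to significance flags, directions and fold-change magnitudes,
and mapped to one of six dynamics classes by an ordered decision table:

1. ``persistent`` — changed during the confrontations and did not
   restore: C_A20 and C_AD significant, same direction, A20_AD not.
2. ``partial_normalization`` — still significantly different from
   control after deprivation but closer to it: all three significant,
   same C-direction, |log2FC(C_AD)| < |log2FC(C_A20)|.
3. ``deprivation_emergent`` — changed only during the deprivation:
   C_A20 not significant, A20_AD and C_AD significant.
4. ``gradual_emergent`` — drifted gradually, significant only in the
   endpoint comparison: C_A20 and A20_AD not significant, C_AD is.
5. ``restored`` — changed during the confrontations, back to control
   after deprivation: C_A20 significant, C_AD not.
6. ``unclassified`` — everything else.

The table is evaluated in order, so it is total and mutually exclusive
by construction.  Direction agreement uses the sign of log2FC, with an
exact zero agreeing with either sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEGTable
from .io import PlsrankError

CLASS_NAMES = (
    "persistent",
    "partial_normalization",
    "deprivation_emergent",
    "gradual_emergent",
    "restored",
    "unclassified",
)


def classify_flags(
    sig_c_a20: bool,
    sig_c_ad: bool,
    sig_a20_ad: bool,
    lfc_c_a20: float,
    lfc_c_ad: float,
) -> str:
    """Pure decision function from one gene's supporting flags."""
    same_direction = lfc_c_a20 * lfc_c_ad >= 0  # zero agrees with either sign
    if sig_c_a20 and sig_c_ad and same_direction and not sig_a20_ad:
        return "persistent"
    if (
        sig_c_a20
        and sig_c_ad
        and same_direction
        and sig_a20_ad
        and abs(lfc_c_ad) < abs(lfc_c_a20)
    ):
        return "partial_normalization"
    if not sig_c_a20 and sig_a20_ad and sig_c_ad:
        return "deprivation_emergent"
    if not sig_c_a20 and not sig_a20_ad and sig_c_ad:
        return "gradual_emergent"
    if sig_c_a20 and not sig_c_ad:
        return "restored"
    return "unclassified"


def classify_trajectory(
    deg_c_a20: DEGTable,
    deg_c_ad: DEGTable,
    deg_a20_ad: DEGTable,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene trajectory calls from the three contrast tables.

    All three contrasts must cover every requested gene (default: the
    C_A20 universe).  Returns a frame with the class and the supporting
    flags that produced it.
    """
    genes = list(deg_c_a20.table.index) if genes is None else list(genes)
    tables = {
        "C_A20": deg_c_a20.table,
        "C_AD": deg_c_ad.table,
        "A20_AD": deg_a20_ad.table,
    }
    for name, t in tables.items():
        missing = [g for g in genes if g not in t.index]
        if missing:
            raise PlsrankError(
                f"contrast {name} is missing gene(s): {', '.join(missing[:5])}"
            )

    sig = {k: t["significant"].loc[genes].to_numpy(bool) for k, t in tables.items()}
    lfc = {k: t["log2fc"].loc[genes].to_numpy(float) for k, t in tables.items()}
    calls = [
        classify_flags(
            sig["C_A20"][i], sig["C_AD"][i], sig["A20_AD"][i],
            lfc["C_A20"][i], lfc["C_AD"][i],
        )
        for i in range(len(genes))
    ]
    return pd.DataFrame(
        {
            "trajectory_class": calls,
            "sig_C_A20": sig["C_A20"],
            "sig_C_AD": sig["C_AD"],
            "sig_A20_AD": sig["A20_AD"],
            "log2fc_C_A20": lfc["C_A20"],
            "log2fc_C_AD": lfc["C_AD"],
            "log2fc_A20_AD": lfc["A20_AD"],
        },
        index=pd.Index(genes, name="gene_id"),
    )
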