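"""Reference chemical panel with the study's reported outcome margins.

The 26-chemical validation panel is reproduced margin-exactly: any
per-chemical assignment with these 2x2 margins yields identical predictivity
metrics, so the panel is generated (seeded) rather than shipped, and no
per-chemical identity is claimed.
"""

from __future__ import annotations

from lungsurf.concordance import ChemicalRecord
from lungsurf.simulate import generate_outcome_dataset

#: (TP, FN, FP, TN) of the in vitro call vs GHS acute inhalation
#: classification (categories 3-4 positive) over the 26-chemical panel.
GHS_MARGINS = (10, 5, 8, 3)
#: (TP, FN, FP, TN) vs clinical signs of respiratory toxicity in rats
#: within 2 h of exposure.
CLINICAL_MARGINS = (17, 4, 1, 4)
N_CHEMICALS = 26


def make_reference_panel(seed: int = 0) -> list[ChemicalRecord]:
    """26-chemical panel whose two-scenario confusion tables match the study."""
    return generate_outcome_dataset(GHS_MARGINS, CLINICAL_MARGINS, N_CHEMICALS, seed=seed)
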