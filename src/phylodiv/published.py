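"""Published intra-specific diversity shares for European butterfly dispersal.

The original study of dispersal diversity in European butterflies reported,
for eight dispersal metrics, the proportion S_c of total trait diversity
attributable to within-species (among-population) variation.  The underlying
dispersal tables and supertree were not deposited, but the printed S_c
column is reproduced here as reference input for summary arithmetic (e.g.
the range of intra- vs inter-specific variability across metrics).
"""

from __future__ import annotations

import numpy as np

# metric -> printed S_c (share of total diversity that is intra-specific)
BUTTERFLY_DISPERSAL_SC: dict[str, float] = {
    "dispersal_fraction": 0.307,
    "alpha1": 0.570,
    "alpha2": 0.127,
    "P5km": 0.188,
    "daily_moves": 0.119,
    "FstL": 0.277,
    "FstR": 0.233,
    "FstC": 0.104,
}


def intra_share_percent_range(sc: dict[str, float] | None = None) -> tuple[float, float]:
    """Smallest and largest intra-specific share, as percentages."""
    values = np.array(list((sc or BUTTERFLY_DISPERSAL_SC).values()))
    return float(values.min() * 100), float(values.max() * 100)


def intra_vs_inter_percent_range(sc: dict[str, float] | None = None) -> tuple[float, float]:
    """Intra-specific variability relative to inter-specific variability.

    For a share S_c, the intra-specific part is S_c and the inter-specific
    part 1 - S_c, so the ratio is S_c / (1 - S_c); returned in percent,
    (min, max) across metrics.
    """
    values = np.array(list((sc or BUTTERFLY_DISPERSAL_SC).values()))
    ratio = values / (1 - values) * 100
    return float(ratio.min()), float(ratio.max())
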