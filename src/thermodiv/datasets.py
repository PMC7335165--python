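"""Small bundled example tables for the worked examples and demos.

These are published per-order results from a large-scale screen of
diversification-temperature association across the 17 rosid orders: the
per-clade Pearson correlations (rho) between mean-annual-temperature
niche and log tip rate with their simulation p-values, and the
state-specific tip speciation rates (non-tropical vs tropical) with
p-values under two tropicality definitions (Koppen-Geiger climatic and
geographic).  NA marks small clades where the binary test failed (e.g.
monomorphic tropicality).  They serve as ready-made inputs for the
multiple-testing correction and the cross-clade replication statistics;
nothing in the package's inference depends on them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "essim_order_screen",
    "fisse_order_screen",
]

_NA = np.nan

_ORDERS = [
    "Brassicales", "Celastrales", "Crossosomatales", "Cucurbitales",
    "Fabales", "Fagales", "Geraniales", "Huerteales", "Malpighiales",
    "Malvales", "Myrtales", "Oxalidales", "Picramniales", "Rosales",
    "Sapindales", "Vitales", "Zygophyllales",
]

_ESSIM_RHO = [
    -0.3945, 0.0185, -0.1255, -0.0471, -0.3290, -0.0767, 0.0655, -0.6484,
    -0.3256, -0.1251, -0.2129, -0.1205, -0.3169, -0.2072, -0.0668, -0.3762,
    -0.0581,
]
_ESSIM_P = [
    0.0180, 0.9444, 0.8011, 0.9290, 0.0060, 0.4985, 0.8117, 0.2413,
    0.0007, 0.4392, 0.1113, 0.5252, 0.7711, 0.2186, 0.5012, 0.1619,
    0.7804,
]

# columns: lambda_non_tropical, lambda_tropical, p  (climatic then geographic)
_FISSE_KOPPEN = [
    (0.5198, 0.1594, 0.0985), (0.2208, 0.2015, _NA), (0.0776, 0.1073, 0.6104),
    (0.3033, 0.2353, 0.2168), (0.6197, 0.2946, 0.0020), (0.6032, 0.3385, 0.0320),
    (0.2919, 0.0544, 0.1578), (0.0278, 0.0195, 0.1718), (0.4105, 0.2312, 0.0230),
    (0.4066, 0.2963, 0.1898), (0.4766, 0.2594, 0.0440), (0.1532, 0.0854, 0.1698),
    (0.0875, 0.0488, 0.1389), (0.6407, 0.3218, 0.0390), (0.2576, 0.2202, 0.1159),
    (0.7599, 0.1055, _NA), (0.0628, 0.0537, 0.2777),
]
_FISSE_GEO = [
    (0.5079, 0.4410, 0.4865), (0.2309, 0.2046, _NA), (0.0893, 0.0477, 0.2248),
    (0.2919, 0.2843, 0.4945), (0.6962, 0.3450, 0.0080), (0.6276, 0.4008, 0.0609),
    (0.2988, 0.2366, 0.2378), (0.0278, 0.0195, 0.1768), (0.4747, 0.2582, 0.0060),
    (0.4305, 0.3639, 0.3666), (0.4972, 0.3544, 0.3437), (0.1815, 0.1503, _NA),
    (_NA, _NA, _NA), (0.6795, 0.4339, 0.1149), (0.2815, 0.2280, 0.1089),
    (0.9223, 0.1014, _NA), (0.0570, 0.0663, 0.7682),
]


def essim_order_screen() -> pd.DataFrame:
    """Per-order continuous-niche correlation screen (rho and raw p)."""
    return pd.DataFrame({"order": _ORDERS, "rho": _ESSIM_RHO, "p": _ESSIM_P}).set_index("order")


def fisse_order_screen(definition: str = "koppen") -> pd.DataFrame:
    """Per-order binary-tropicality rate screen.

    ``definition``: ``koppen`` (climatic) or ``geographic``.  Columns:
    lambda0 (tropical), lambda1 (non-tropical), p.
    """
    data = {"koppen": _FISSE_KOPPEN, "geographic": _FISSE_GEO}.get(definition)
    if data is None:
        raise ValueError("definition must be 'koppen' or 'geographic'")
    lam_nt, lam_t, p = zip(*data)
    return pd.DataFrame(
        {"order": _ORDERS, "lambda1": lam_nt, "lambda0": lam_t, "p": p}
    ).set_index("order")
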