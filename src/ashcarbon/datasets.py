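"""Bundled reference summary of the motivating incubation experiment.

These are the day-118 treatment means and standard errors (n = 3) from the
straw / wood-ash calcareous-soil incubation that this package models. They
serve two purposes: worked-example inputs for the pool-accounting arithmetic
(percent changes, SIC balance, CO2 contrasts) and the default effect
structure of the synthetic generator.

Units: cumulative CO2-C in g kg-1; SOC and SIC in g C kg-1; MBC, DOC,
water-soluble cations and mineral N in mg kg-1; TN in g kg-1; EC in uS cm-1;
moisture as a gravimetric fraction; hydrolytic enzymes (bxyl, bg, cbh) in
nmol h-1 g-1; invertase and catalase in mg g-1 d-1; dehydrogenase in
mg kg-1 h-1.
"""

from __future__ import annotations

import pandas as pd

from .core import TREATMENTS

__all__ = ["reference_pool_means", "reference_pool_ses"]

_MEANS = {
    #                 Control     W       S      SW
    "cum_co2_c":      (0.9,     0.7,    5.0,    4.7),
    "soc":            (8.42,    8.35,   9.66,   9.84),
    "sic":            (8.35,    9.00,   8.35,   9.00),
    "mbc":            (180.0,   205.0,  364.0,  438.0),
    "doc":            (50.9,    69.9,   84.8,   107.9),
    "moisture":       (0.246,   0.247,  0.259,  0.258),
    "ws_ca":          (286.0,   318.0,  282.0,  249.0),
    "ws_k":           (0.3,     20.3,   23.6,   22.5),
    "ws_mg":          (21.6,    28.9,   27.5,   44.5),
    "ph":             (7.94,    8.07,   8.04,   8.16),
    "ec":             (180.0,   619.0,  379.0,  608.0),
    "tn":             (1.2,     1.2,    1.3,    1.3),
    "min_n":          (79.8,    80.1,   61.9,   58.6),
    "bxyl":           (7.0,     5.8,    10.8,   9.7),
    "bg":             (18.3,    16.1,   23.6,   22.4),
    "cbh":            (6.7,     4.6,    8.8,    7.4),
    "invertase":      (52.1,    53.5,   59.7,   69.1),
    "catalase":       (1.2,     0.9,    1.1,    1.2),
    "dehydrogenase":  (7.2,     5.6,    16.8,   20.7),
}

_SES = {
    "cum_co2_c":      (0.01,  0.01,  0.01,  0.01),
    "soc":            (0.10,  0.20,  0.10,  0.20),
    "sic":            (0.30,  0.20,  0.10,  0.20),
    "mbc":            (1.5,   1.4,   4.2,   1.9),
    "doc":            (2.8,   3.0,   5.0,   3.7),
    "moisture":       (0.001, 0.001, 0.001, 0.001),
    "ws_ca":          (5.1,   31.9,  40.2,  16.5),
    "ws_k":           (0.1,   0.6,   2.4,   4.1),
    "ws_mg":          (8.2,   6.7,   17.0,  13.0),
    "ph":             (0.07,  0.02,  0.10,  0.02),
    "ec":             (1.5,   34.9,  12.8,  33.5),
    "tn":             (0.02,  0.02,  0.02,  0.02),
    "min_n":          (0.5,   0.1,   1.3,   3.3),
    "bxyl":           (0.1,   0.6,   2.0,   1.6),
    "bg":             (0.5,   1.0,   2.1,   0.3),
    "cbh":            (0.4,   0.4,   0.2,   0.5),
    "invertase":      (5.2,   10.6,  3.4,   1.2),
    "catalase":       (0.04,  0.05,  0.04,  0.05),
    "dehydrogenase":  (0.8,   0.6,   1.3,   0.6),
}


def reference_pool_means() -> pd.DataFrame:
    """Treatment-mean reference table (rows = treatments, columns = variables)."""
    return pd.DataFrame(_MEANS, index=list(TREATMENTS))


def reference_pool_ses() -> pd.DataFrame:
    """Standard errors (n = 3) matching :func:`reference_pool_means`."""
    return pd.DataFrame(_SES, index=list(TREATMENTS))
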