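"""Packaged per-condition dynamic-instability parameter tables.

Two reference tables ship with the package as CSV: porcine brain tubulin
(12 uM, TIRF) and budding-yeast tubulin (4 uM, DIC), each giving the
measured growth rate, catastrophe frequency and (for porcine) shrinkage
rate and rescue frequency, with standard errors and event counts, across
Kip2 concentrations 0-40 nM.  Blank cells are conditions in which
catastrophes were too rare for the quantity to be measured.

The yeast table reports no shrinkage or rescue values; for simulation the
package substitutes a nominal shrink rate of 25 um/min and rescue
frequency 0 (see :func:`generating_params`), and porcine 20/40 nM rows
similarly substitute 28 um/min and 0.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .params import DynamicsParams

__all__ = ["load_table", "condition_params", "generating_params"]

_FILES = {"porcine": "table1_porcine.csv", "yeast": "table2_yeast.csv"}

#: Substitutes used only when *simulating* a condition whose shrink/rescue
#: cells are blank (never reported back as measurements).
_NOMINAL_SHRINK = {"porcine": 28.0, "yeast": 25.0}


def load_table(species: str) -> pd.DataFrame:
    """Return the packaged parameter table for ``species``
    ('porcine' or 'yeast') as a DataFrame indexed by Kip2 concentration."""
    try:
        fname = _FILES[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}; expected 'porcine' or 'yeast'")
    with resources.files("kip2mt.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("kip2_nM", drop=False)


def condition_params(row: pd.Series) -> DynamicsParams:
    """Dynamic-instability parameters exactly as printed in a table row.

    Missing shrink/rescue cells become 0 (meaning: not measured / never
    observed), so the returned object is faithful to the table, not
    necessarily simulable as-is.
    """
    def get(col):
        v = row.get(col)
        return 0.0 if v is None or pd.isna(v) else float(v)

    return DynamicsParams(
        growth_rate=get("growth_rate"),
        catastrophe_freq=get("cat_freq"),
        shrink_rate=get("shrink_rate"),
        rescue_freq=get("rescue_freq"),
    )


def generating_params(row: pd.Series, species: str) -> DynamicsParams:
    """Simulation-ready parameters for a table row.

    Identical to :func:`condition_params` except that a blank shrinkage
    rate is replaced by the species' nominal value, so that catastrophes
    (however rare) are followed by a finite shrinkage phase.
    """
    d = condition_params(row)
    if d.shrink_rate == 0:
        d = DynamicsParams(
            growth_rate=d.growth_rate,
            catastrophe_freq=d.catastrophe_freq,
            shrink_rate=_NOMINAL_SHRINK[species],
            rescue_freq=d.rescue_freq,
        )
    return d
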