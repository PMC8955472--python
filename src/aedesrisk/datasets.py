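"""Bundled reference tables.

The Ticino surveillance bookkeeping table (yearly counts of ovitraps
analyzed, ovitraps with establishment, cells observed and cells with
establishment, 2004-2015) is the published aggregate of the long-term
*Ae. albopictus* monitoring program; the underlying trap records are not
public.  The table is used to check split bookkeeping: years 2005-2012
formed the training set (4282 observed cells, 990 established), 2013-2015
the validation set (2961 cells, 1608 established), and 2004 seeded the
dispersal feature only.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_ticino_summary", "TICINO_TRAIN_YEARS", "TICINO_TEST_YEARS"]

TICINO_TRAIN_YEARS = tuple(range(2005, 2013))
TICINO_TEST_YEARS = (2013, 2014, 2015)


def load_ticino_summary() -> pd.DataFrame:
    """Yearly Ticino surveillance counts (2004-2015), one row per year."""
    ref = resources.files("aedesrisk.data").joinpath("ticino_surveillance.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
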