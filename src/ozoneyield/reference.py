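"""Published reference tables shipped with the package.

Currently one table: the per-sub-region seasonal production losses of beans
to ozone in Uganda, 2015 (tonnes).  It serves as a fixed input for checking
the loss-table aggregation arithmetic against published national totals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["uganda_production_losses_2015"]


def uganda_production_losses_2015() -> pd.DataFrame:
    """Per-sub-region seasonal bean production losses (t), Uganda 2015.

    Columns: sub_region, region, season1, season2; the unimodal Karamoja
    sub-region has its single-season loss in the season1 column and NaN in
    season2.
    """
    with resources.files("ozoneyield.data").joinpath(
        "uganda_bean_production_loss_2015.csv"
    ).open() as fh:
        return pd.read_csv(fh, comment="#")
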