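"""Bundled reference dataset: volatile profiles of *Docynia delavayi* fruit.

The package ships a curated table of the published volatile-compound profiles
of young (DY) and mature (DM) *D. delavayi* fruit — 42 identified compounds
with mean relative contents per maturity stage, odor thresholds and aroma
descriptors for the 14 aroma-active key compounds, and the published VIP and
p-value columns for the 23 differential key compounds.

Since only group means were published, the peak table carries one
pseudo-replicate per group whose "areas" are the mean relative contents in
percent.  Relative quantification is scale-invariant per sample, so
downstream ratios are unaffected; multivariate refits that need genuine
replicates are not possible from this table (use the published VIP/p columns
for the screening stage instead).
"""

from __future__ import annotations

from importlib import resources
from typing import NamedTuple

import pandas as pd

from .io import read_peak_table, read_threshold_table
from .model import PeakTable, ThresholdTable

__all__ = ["DocyniaDataset", "docynia_fruit"]


class DocyniaDataset(NamedTuple):
    """Curated D. delavayi fruit tables (young vs. mature)."""

    peaks: PeakTable
    thresholds: ThresholdTable
    vip_table: pd.DataFrame  # columns: id, name, vip, p


def _data_path(name: str):
    return resources.files("flavoromics.data").joinpath(name)


def docynia_fruit() -> DocyniaDataset:
    """Load the bundled *D. delavayi* young/mature fruit dataset.

    Returns the 42-compound peak table (one mean pseudo-replicate per group,
    areas on the percent scale), the 14-compound odor-threshold/descriptor
    table, and the published per-compound VIP/p screening columns.
    """
    with resources.as_file(_data_path("docynia_peaks.csv")) as p_peaks, \
            resources.as_file(_data_path("docynia_samples.csv")) as p_samples:
        peaks = read_peak_table(str(p_peaks), str(p_samples))
    with resources.as_file(_data_path("docynia_thresholds.csv")) as p_thr:
        thresholds = read_threshold_table(str(p_thr))
    with resources.as_file(_data_path("docynia_vip.csv")) as p_vip:
        vip = pd.read_csv(str(p_vip), dtype={"id": str, "name": str})
    return DocyniaDataset(peaks=peaks, thresholds=thresholds, vip_table=vip)
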