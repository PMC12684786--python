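"""Bundled example data.

The package ships one *synthetic* example: a 26-variant cis instrument
table in the canonical summary-statistics dialect together with its LD
matrix, generated by :mod:`cismr.simulate` (see the adjacent ``.meta.yaml``
for the generating parameters).  It exists so the instrument-selection and
MR machinery can be exercised without downloading real GWAS data; it is not
real data.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .instruments import LDMatrix
from .sumstats import SumStatTable, read_sumstats


def _data_path(name: str):
    return resources.files("cismr").joinpath("data", name)


def load_example_instruments() -> SumStatTable:
    """The synthetic 26-variant cis instrument table (exposure associations)."""
    with resources.as_file(_data_path("instrument_26_synthetic.tsv")) as path:
        return read_sumstats(path, trait_label="ln_biomarker")


def load_example_ld() -> LDMatrix:
    """The companion synthetic LD (r^2) matrix."""
    with resources.as_file(_data_path("ld_26_synthetic.tsv")) as path:
        return LDMatrix.read(path)


def load_example_metadata() -> dict:
    """Generating parameters of the synthetic example (from its meta file)."""
    return yaml.safe_load(_data_path("instrument_26_synthetic.meta.yaml").read_text())
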