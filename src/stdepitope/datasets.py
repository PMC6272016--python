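"""Packaged experimental reference tables (FNR–dinucleotide STD study).

Three published epitope tables for complexes of ferredoxin-NADP+
reductase (wild type and the Y303S / PP3CT mutants) with NADP+ and NAD+
ship with the package as TSV resources:

- ``table1``: absolute fractional STD of the adenosine A2 proton at 2 s
  saturation, per complex (percent).
- ``table2``: relative STD at 2 s saturation, normalized to 100 % per
  ligand (percent).
- ``table3``: relative STD initial growing rates (initial slopes),
  normalized to 100 % (percent).

Empty/unmeasured cells are encoded as NA.  Proton labels follow the
dinucleotide convention: A* adenine/adenosine ribose, N* nicotinamide
and its ribose.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .buildup import EpitopeMap

__all__ = ["load_table", "epitope_from_table"]

_FILES = {
    "table1": "table1_absolute_std_a2.tsv",
    "table2": "table2_relative_std_2s.tsv",
    "table3": "table3_relative_std0.tsv",
}


def load_table(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables by name.

    ``table2``/``table3`` are indexed by proton label; ``table1`` by
    complex name.
    """
    if name not in _FILES:
        raise KeyError(f"unknown table {name!r}; choose from {sorted(_FILES)}")
    ref = resources.files("stdepitope.data").joinpath(_FILES[name])
    with ref.open("r") as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    df = df.set_index(df.columns[0])
    return df


def epitope_from_table(name: str, complex_name: str) -> EpitopeMap:
    """Extract one complex's column of table2/table3 as an EpitopeMap,
    dropping NA cells."""
    df = load_table(name)
    if complex_name not in df.columns:
        raise KeyError(
            f"complex {complex_name!r} not in {name}; choose from {list(df.columns)}"
        )
    col = df[complex_name].dropna()
    ref = col.index[int(col.to_numpy().argmax())]
    return EpitopeMap(values={str(k): float(v) for k, v in col.items()},
                      reference_id=str(ref))
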