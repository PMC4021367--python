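"""Bundled reference data.

* ``reported_amino_acid_fluxes()`` — the published consumption/production
  pattern of amino acids during exponential growth of *Thermus
  thermophilus* HB27 on amino-acid-rich complex medium (mmol gDCW^-1
  h^-1; positive supply = consumed from the medium).  The four columns
  obey the steady-state row identity supply + from_others = demand +
  to_others, which `thermoflux.compare.close_balance_row` exploits.

* ``thermus_reference()`` — headline reconstruction statistics and
  simulation parameters for the HB27 genome-scale network (gene /
  reaction / ORF counts, maintenance values, GC content).
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files(__package__) / "data" / name


def reported_amino_acid_fluxes() -> pd.DataFrame:
    """Amino-acid supply/demand/conversion table, indexed by amino acid."""
    with resources.as_file(_data_path(
            "complex_medium_amino_acid_fluxes.tsv")) as path:
        return pd.read_csv(path, sep="\t", index_col="amino_acid")


def thermus_reference() -> dict:
    """Reference counts and parameters for the HB27 network."""
    with resources.as_file(_data_path("thermus_reference.json")) as path:
        return json.loads(path.read_text())


def orf_coverage_percent(model_genes: int, genome_orfs: int) -> float:
    """Share of genome ORFs captured by a metabolic model, in percent."""
    if genome_orfs <= 0:
        raise ValueError("genome ORF count must be positive")
    return 100.0 * model_genes / genome_orfs
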