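"""Published accounting for the Asian seabass LG2 target region.

The bundled table records, per screening SSR marker / FPC contig: its
genetic position, the number of positive clones found in the 3D pool
screen, the MTP size, the physical-map expected size (CB units converted at
1.36 kb/CB), and the scaffold count and assembly size of the short-read-only
and hybrid assemblies.  Project-level constants of the same study design
(library size, pool layout, read yield, BES outcomes) are exposed here so
summary arithmetic can be recomputed from first principles.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_table", "STUDY"]

#: Project-level constants of the LG2 targeted-sequencing study design.
STUDY = {
    "library_n_clones": 49_152,
    "physmap_n_clones": 35_265,
    "mean_insert_kb": 98.0,
    "genome_mb": 700.0,
    "pool_design": (100, 16, 24),
    "n_markers_screened": 22,
    "n_mtp_clones": 72,
    "total_cb_units": 5_177,
    "kb_per_cb": 1.36,
    "lg2_cm": 97.0,
    "rate_cm_per_mb": 3.4,
    "lg2_mb_stated": 28.7,  # as stated from the linkage map (see docs)
    "n_short_reads": 3_800_000,
    "mean_read_len_bp": 241.9,
    "bes_ends_passing": 140,
    "bes_ends_attempted": 144,
    "bes_clones_both_ends": 68,
    "n_genes_total": 257,
    "n_genes_annotated": 195,
}


def load_reference_table() -> pd.DataFrame:
    """Per-marker/contig accounting table (see module docstring)."""
    with resources.files("bacpool.data").joinpath("lg2_reference_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
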