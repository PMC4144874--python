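"""The 90-region AAL node table used as network nodes.

The Automated Anatomical Labeling (AAL) parcellation divides the cerebrum
into 45 paired cortical and sub-cortical regions (90 nodes, 45 per
hemisphere). Left/right instances of a region carry the ``_L``/``_R``
suffix on its abbreviation, e.g. ``SMA_L`` for the left supplementary
motor area.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["AAL_REGIONS", "default_node_table", "load_node_table", "write_node_table"]

# (region name, abbreviation) for the 45 paired AAL regions.
AAL_REGIONS: tuple[tuple[str, str], ...] = (
    ("Superior frontal gyrus, dorsolateral", "SFGdor"),
    ("Superior frontal gyrus, orbital", "SFGorb"),
    ("Superior frontal gyrus, medial", "SFGmed"),
    ("Superior frontal gyrus, medial orbital", "SFGmorb"),
    ("Middle frontal gyrus", "MFG"),
    ("Middle frontal gyrus, orbital", "MFGorb"),
    ("Inferior frontal gyrus, opercular", "IFGoper"),
    ("Inferior frontal gyrus, triangular", "IFGtri"),
    ("Inferior frontal gyrus, orbital", "IFGorb"),
    ("Gyrus rectus", "REG"),
    ("Anterior cingulate gyrus", "ACC"),
    ("Olfactory cortex", "OLF"),
    ("Precentral gyrus", "PreCG"),
    ("Supplementary motor area", "SMA"),
    ("Rolandic operculum", "ROL"),
    ("Median- and para-cingulate gyrus", "MCC"),
    ("Calcarine fissure and surrounding cortex", "CAL"),
    ("Cuneus", "CUN"),
    ("Lingual gyrus", "LING"),
    ("Superior occipital gyrus", "SOG"),
    ("Middle occipital gyrus", "MOG"),
    ("Inferior occipital gyrus", "IOG"),
    ("Fusiform gyrus", "FG"),
    ("Superior parietal gyrus", "SPG"),
    ("Paracentral lobule", "PCL"),
    ("Postcentral gyrus", "PoCG"),
    ("Inferior parietal gyrus", "IPG"),
    ("Supramarginal gyrus", "SMG"),
    ("Angular gyrus", "ANG"),
    ("Precuneus", "PCNU"),
    ("Posterior cingulate gyrus", "PCC"),
    ("Insula", "INS"),
    ("Thalamus", "THA"),
    ("Superior temporal gyrus", "STG"),
    ("Superior temporal gyrus, temporal pole", "STGp"),
    ("Middle temporal gyrus", "MTG"),
    ("Middle temporal gyrus, temporal pole", "MTGp"),
    ("Inferior temporal gyrus", "ITG"),
    ("Heschl gyrus", "HES"),
    ("Hippocampus", "HIP"),
    ("Parahippocampal gyrus", "PHIP"),
    ("Amygdala", "AMYG"),
    ("Caudate nucleus", "CAU"),
    ("Lenticular nucleus, putamen", "PUT"),
    ("Lenticular nucleus, pallidum", "PAL"),
)

_COLUMNS = ["index", "name", "abbreviation", "hemisphere"]


def default_node_table() -> pd.DataFrame:
    """Built-in 90-row AAL node table (left then right for each region)."""
    rows = []
    idx = 1
    for name, abbr in AAL_REGIONS:
        for hemi in ("L", "R"):
            rows.append((idx, name, f"{abbr}_{hemi}", hemi))
            idx += 1
    return pd.DataFrame(rows, columns=_COLUMNS)


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    if list(table.columns) != _COLUMNS:
        raise ValueError(
            f"node table must have columns {_COLUMNS}, got {list(table.columns)}"
        )
    abbrs = table["abbreviation"]
    if abbrs.duplicated().any():
        dupes = sorted(abbrs[abbrs.duplicated()].unique())
        raise ValueError(f"duplicate abbreviations in node table: {dupes}")
    return table


def load_node_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a node table from CSV, or return the built-in AAL table."""
    if path is None:
        return default_node_table()
    table = pd.read_csv(path, dtype={"index": int, "name": str,
                                     "abbreviation": str, "hemisphere": str})
    return _validate(table)


def write_node_table(table: pd.DataFrame, path: str | Path) -> None:
    _validate(table).to_csv(path, index=False)
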