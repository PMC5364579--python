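"""Small bundled observation tables from a deep-subsurface biofilm survey.

Two in-memory datasets support worked examples and end-to-end checks without
any download: the published relative-abundance table of 16S rRNA OTUs across
planktonic and biofilm habitats in two Fennoscandian shield groundwater
types ("modern marine" and "old saline"), and the ATP-derived cell-density
observations for the same flow-cell experiment.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["subsurface_otu_percent_table", "cell_density_observations"]

_OTU_ROWS = [
    # taxon, MM_planktonic, MM_garnet, MM_glass, OS_planktonic, OS_garnet, OS_glass
    ("Unknown phylum", 29.4, 7.51, 13.0, 50.0, 2.54, 3.05),
    ("Actinobacteria", 0, 0, 0, 1.62, 0, 0),
    ("Atribacteria", 1.18, 0, 0, 20.6, 0, 0),
    ("Gracilibacteria", 5.30, 9.85, 2.16, 0, 0, 0),
    ("Gammaproteobacteria", 12.3, 7.89, 4.44, 0, 0, 0),
    ("Thermoplasmata", 0, 0, 0, 2.75, 0, 0),
    ("Desulfuromonadales", 0, 0, 0, 0, 0, 1.21),
    ("Ignavibacteriales", 0, 0, 0, 8.13, 0, 0),
    ("Myxococcales", 0, 0, 0, 0, 1.29, 1.37),
    ("Hydrogenophilaceae", 0, 0, 1.30, 0, 0, 0),
    ("Rhodocyclaceae", 0, 1.57, 0, 0, 15.7, 27.6),
    ("Desulfatiglans", 3.30, 0, 0, 0, 0, 0),
    ("Desulfobulbus", 0, 3.22, 0, 0, 0, 0),
    ("Desulfocapsa", 0, 0, 0, 0, 5.33, 8.74),
    ("Ferritrophicum", 0, 3.07, 1.32, 0, 0, 0),
    ("Marichromatium", 1.86, 0, 0, 0, 0, 0),
    ("Sideroxydans", 0, 0, 2.95, 0, 0, 0),
    ("Sulfurimonas", 0, 48.7, 50.9, 0, 68.2, 50.6),
    ("Sulfurovum", 0, 3.78, 8.41, 0, 0, 0),
    ("Syntrophus", 3.78, 0, 0, 2.40, 0, 0),
    ("Candidate division OP3", 12.6, 0, 3.21, 0, 0, 0),
    ("Candidate Nitrotoga", 0, 4.59, 4.50, 0, 0, 1.11),
    ("Omnitrophica", 0, 0, 0, 1.15, 0, 0),
    ("Parcubacteria", 11.7, 0, 0, 7.54, 0, 0),
    ("TA06", 0, 0, 1.22, 0, 0, 0),
    ("<1%", 18.6, 9.80, 6.58, 5.78, 6.92, 6.26),
]

_OTU_SAMPLES = [
    "MM_planktonic",
    "MM_garnet",
    "MM_glass",
    "OS_planktonic",
    "OS_garnet",
    "OS_glass",
]


def subsurface_otu_percent_table() -> pd.DataFrame:
    """Relative abundance (%) of 16S rRNA OTUs, taxa >=1% shown in detail.

    Columns are the six habitats: planktonic water, garnet-grain biofilm and
    glass-bead biofilm for the modern marine (MM) and old saline (OS) water
    types.  Taxa below 1% in every habitat are pooled in the ``<1%`` row, so
    each column sums to ~100.
    """
    df = pd.DataFrame(_OTU_ROWS, columns=["taxon"] + _OTU_SAMPLES)
    return df.set_index("taxon")


def cell_density_observations() -> pd.DataFrame:
    """ATP-derived cell densities from the same flow-cell experiment.

    Biofilm entries are cells cm^-2 on the sampled surface; planktonic
    entries are cells mL^-1 of borehole water (the old saline planktonic
    value is an estimate from an adjacent borehole of similar chemistry).
    """
    rows = [
        ("MM_garnet_biofilm", 4.6e6, "cells/cm^2"),
        ("MM_glass_biofilm", 2.0e8, "cells/cm^2"),
        ("OS_garnet_biofilm", 1.9e4, "cells/cm^2"),
        ("OS_glass_biofilm", 4.3e3, "cells/cm^2"),
        ("MM_planktonic", 2.8e4, "cells/mL"),
        ("OS_planktonic", 1.0e2, "cells/mL"),
    ]
    return pd.DataFrame(rows, columns=["sample_id", "density", "units"]).set_index(
        "sample_id"
    )
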