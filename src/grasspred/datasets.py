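"""Published benchmark numbers for the Miscanthus sinensis diversity panel.

The panel behind this package's design is a field trial of 138 outbred
*M. sinensis* genotypes phenotyped for 17 traits and genotyped with RAD-Seq
SNVs called against two references (*Sorghum bicolor* and a *Miscanthus*
pseudo-reference).  The raw data are not public; what is public are the
printed per-trait summaries: broad-sense heritabilities and the mean
predictive abilities/accuracies of ridge-regression prediction under 100
random 10-fold cross-validations.  Those printed values are shipped here as
reference inputs — e.g. as heritability targets for the demo data generator
and for checking arithmetic identities such as ``Accu = r / sqrt(H2)``.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["trait_benchmark", "N_MARKERS_SORGHUM", "N_MARKERS_MISCANTHUS"]

#: liberal-filter marker panel sizes for the two reference alignments
N_MARKERS_SORGHUM = 53_174
N_MARKERS_MISCANTHUS = 121_771

_TRAIT_ROWS = [
    # trait, group, h2, r_sorg, accu_sorg, r_misc, accu_misc
    ("DOYFS1.9",          "phenology",  0.89, 0.76, 0.81, 0.78, 0.82),
    ("AvgeSen.9",         "phenology",  0.83, 0.64, 0.71, 0.64, 0.71),
    ("BaseDiameter.9",    "morphology", 0.52, 0.27, 0.38, 0.29, 0.40),
    ("DryMatter.9",       "morphology", 0.54, 0.06, 0.09, 0.04, 0.05),
    ("LeafLength.7",      "morphology", 0.65, 0.67, 0.83, 0.66, 0.82),
    ("LeafWidth.7",       "morphology", 0.64, 0.52, 0.65, 0.56, 0.70),
    ("MaxCanopyHeight.9", "morphology", 0.77, 0.35, 0.40, 0.34, 0.39),
    ("Moisture.9",        "morphology", 0.59, 0.70, 0.92, 0.73, 0.95),
    ("StatureCategory.7", "morphology", 0.48, 0.39, 0.57, 0.43, 0.62),
    ("StatureLeafAngle.7", "morphology", 0.50, 0.46, 0.65, 0.47, 0.66),
    ("StatureStemAngle.7", "morphology", 0.48, 0.37, 0.53, 0.40, 0.58),
    ("StemDiameter.9",    "morphology", 0.60, 0.51, 0.66, 0.50, 0.65),
    ("TallestStem.9",     "morphology", 0.88, 0.65, 0.69, 0.63, 0.68),
    ("TransectCount.9",   "morphology", 0.51, 0.17, 0.23, 0.27, 0.39),
    ("Cellulose.8",       "cell wall",  0.79, 0.62, 0.70, 0.61, 0.69),
    ("Hemicellulose.8",   "cell wall",  0.60, 0.25, 0.32, 0.18, 0.24),
    ("Lignin.8",          "cell wall",  0.66, 0.43, 0.53, 0.35, 0.43),
]


def trait_benchmark() -> pd.DataFrame:
    """Printed per-trait benchmark values for the 17-trait panel.

    Columns: ``trait``, ``group``, ``h2`` (broad-sense heritability),
    ``r_sorg``/``accu_sorg`` and ``r_misc``/``accu_misc`` (mean predictive
    ability and accuracy over 100 random 10-fold cross-validations for the
    two marker panels).
    """
    return pd.DataFrame(
        _TRAIT_ROWS,
        columns=["trait", "group", "h2", "r_sorg", "accu_sorg",
                 "r_misc", "accu_misc"],
    )
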