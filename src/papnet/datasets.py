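"""Published reference values from the poplar bent-root proteome study.

The pipeline was designed around a study in which 66 differentially
represented bent-root protein spots were k-means-clustered into six
abundance-profile clusters (I-VI) and mapped onto the Populus trichocarpa
STRING interactome. The study's printed summary numbers are embedded here as
worked-example inputs: the six cluster centroids over the six conditions,
cluster sizes and within-cluster sums of squares, the bold sector calls at
threshold 0.3, and the per-subnetwork lists of namespace-specific GO terms
with the accompanying shared counts. GO term *identities* beyond these lists
depend on external database releases and are not modelled.
"""

from __future__ import annotations

import pandas as pd

from .profiles import CONDITIONS

CLUSTER_LABELS: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI")

#: Published per-cluster protein counts; they sum to the 66 input spots.
CLUSTER_SIZES: dict[str, int] = {
    "I": 12, "II": 4, "III": 11, "IV": 3, "V": 16, "VI": 20,
}

#: Published within-cluster sums of squared distances (log2 units squared).
CLUSTER_WITHINSS: dict[str, float] = {
    "I": 36.9506, "II": 42.15465, "III": 38.7308,
    "IV": 42.71795, "V": 65.03039, "VI": 137.90456,
}

_CENTROIDS = {
    "I":   (0.7581557, -0.29911, -2.06396, 0.191851, 0.266578, -1.21004),
    "II":  (-0.1136721, -6.2065, -4.59749, 0.250547, -0.32258, 0.729957),
    "III": (-0.7552579, 0.793721, 0.46037, -0.56888, 0.069973, -6.89288),
    "IV":  (1.0195613, -2.84078, -3.94615, 0.464451, 0.864264, -7.14603),
    "V":   (0.4441395, -1.41837, -0.12500, 0.422867, 0.09185, -1.34692),
    "VI":  (-0.3790747, -0.02729, 0.300643, -0.92325, -0.24844, -0.05900),
}

#: Published bold sector calls (centroid >= 0.3) for each cluster.
SECTOR_CALLS: dict[str, tuple[str, ...]] = {
    "I": ("ABS-cx",),
    "II": ("BBS-cv",),
    "III": ("BS-cx", "BBS-cx"),
    "IV": ("ABS-cx", "ABS-cv", "BS-cv"),
    "V": ("ABS-cx", "ABS-cv"),
    "VI": ("BBS-cx",),
}


def published_centroids() -> pd.DataFrame:
    """The six published cluster centroids (log2 units), I-VI x conditions."""
    return pd.DataFrame.from_dict(
        _CENTROIDS, orient="index", columns=list(CONDITIONS)
    ).loc[list(CLUSTER_LABELS)]


#: Published subnetwork-specific GO terms per namespace and cluster.
SPECIFIC_GO_TERMS: dict[str, dict[str, tuple[str, ...]]] = {
    "biological_process": {
        "I": (
            "GO:0046940", "GO:0009141", "GO:0009123", "GO:0009144",
            "GO:0009199", "GO:0009142", "GO:0009201", "GO:0009058",
            "GO:0006979", "GO:1901576", "GO:0000461",
        ),
        "II": ("GO:0050896", "GO:0042221"),
        "III": (
            "GO:0006086", "GO:0006085", "GO:0035384", "GO:0034033",
            "GO:0006084", "GO:0033866", "GO:0071616", "GO:0034030",
            "GO:0044088", "GO:0032889", "GO:1901652", "GO:0071375",
            "GO:0032869", "GO:1901653", "GO:0032868", "GO:0043434",
            "GO:0044282", "GO:0006793", "GO:0006796", "GO:0016310",
            "GO:1901616", "GO:0046174", "GO:0046164",
        ),
        "IV": (
            "GO:0051179", "GO:0098655", "GO:1902600", "GO:0006812",
            "GO:0098660", "GO:0034220", "GO:0098662", "GO:0006811",
            "GO:0055085", "GO:0006810", "GO:0051234",
        ),
        "V": (
            "GO:0010499", "GO:0043632", "GO:0030163", "GO:0043161",
            "GO:0010498", "GO:0044265", "GO:0006511", "GO:0044257",
            "GO:0051603", "GO:0019941", "GO:2000144", "GO:0045899",
            "GO:0060260", "GO:0045898", "GO:0060261", "GO:0043933",
            "GO:0006807", "GO:0044238", "GO:0071704", "GO:0006508",
            "GO:0044267", "GO:0019538", "GO:1901565", "GO:0009057",
            "GO:0044248",
        ),
        "VI": ("GO:0070887", "GO:0009060"),
    },
    "molecular_function": {
        "I": ("GO:0030570", "GO:0016837", "GO:0008379"),
        "II": (
            "GO:0004364", "GO:0016765", "GO:1900750", "GO:0043295",
            "GO:0072341", "GO:1901681", "GO:0042277", "GO:0033218",
            "GO:0015036", "GO:0016667", "GO:0016740", "GO:0005515",
            "GO:0015035",
        ),
        "III": (
            "GO:0016624", "GO:0051287", "GO:0004634", "GO:0042132",
            "GO:0016860",
        ),
        "IV": (
            "GO:0046961", "GO:0044769", "GO:0042625", "GO:0009678",
            "GO:0019829", "GO:0015078", "GO:0042626", "GO:0015399",
            "GO:0016887", "GO:0022853", "GO:0022890", "GO:0008324",
            "GO:0022804", "GO:0015318", "GO:0015075", "GO:0022857",
            "GO:0005215", "GO:0008553",
        ),
        "V": (
            "GO:0004298", "GO:0070003", "GO:0004175", "GO:0008233",
            "GO:0036402",
        ),
        "VI": (
            "GO:0008135", "GO:0090079", "GO:0045182", "GO:0030060",
            "GO:0016615",
        ),
    },
    "cellular_component": {
        "III": (
            "GO:1990204", "GO:0070469", "GO:0031975", "GO:0031967",
            "GO:0005746", "GO:0005747", "GO:0019866", "GO:0098803",
            "GO:0005743", "GO:0005740", "GO:0031966", "GO:0045271",
            "GO:0030964",
        ),
        "IV": (
            "GO:0016469", "GO:0033176", "GO:0033179", "GO:0033177",
            "GO:0033180", "GO:0005773", "GO:0005774", "GO:0098588",
            "GO:0031090",
        ),
        "V": (
            "GO:0000502", "GO:1905368", "GO:0031597", "GO:0005838",
            "GO:0019773", "GO:0022624", "GO:0008541", "GO:0005839",
            "GO:0008540", "GO:1905369", "GO:0140535",
        ),
    },
}

#: Published counts of GO terms shared among >= 2 subnetworks, per namespace.
SHARED_GO_COUNTS: dict[str, int] = {
    "biological_process": 91,
    "molecular_function": 28,
    "cellular_component": 26,
}

#: Published sizes of the namespace-wise unions ("without overlaps").
UNIQUE_GO_TOTALS: dict[str, int] = {
    "biological_process": 165,
    "molecular_function": 77,
    "cellular_component": 59,
}
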