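"""Bundled reduced pathway networks for the five schizophrenia-associated pathways.

Gene lists and node counts follow the reduced KEGG representations of the
serine biosynthesis, PI3K-Akt, MAPK, neurotrophin and focal adhesion
pathways (5, 11, 11, 9 and 11 nodes; 5, 17, 20, 11 and 27 genes).  Complex
nodes group paralog families or protein-complex subunits, which is what
makes alternative single-gene models multiply (1, 12, 192, 3 and 1296
alternatives respectively).

The *edge topologies* are reconstructed from KEGG biology and should be
treated as a best-effort default; the engine accepts any user-supplied
topology in their place.  Gene symbols are stored verbatim, including
"MAP8/MAP9/MAP10" for the JNK-family node (probably intended as MAPK8/9/10).
"""

from __future__ import annotations

from .networks import PathwayNetwork, PathwayNode


def serine_biosynthesis() -> PathwayNetwork:
    """Serine biosynthesis: linear synthesis chain feeding the two SHMT paralogs."""
    nodes = [PathwayNode(g, (g,)) for g in ("PHGDH", "PSAT1", "PSPH", "SHMT1", "SHMT2")]
    edges = [
        ("PHGDH", "PSAT1"),
        ("PSAT1", "PSPH"),
        ("PSPH", "SHMT1"),
        ("PSPH", "SHMT2"),
    ]
    return PathwayNetwork("serine_biosynthesis", nodes, edges)


def pi3k_akt() -> PathwayNetwork:
    """PI3K-Akt signaling reduced to the AKT3 regulatory core (11 nodes, 17 genes)."""
    nodes = [
        PathwayNode("IRS1", ("IRS1",)),
        PathwayNode("PTK2", ("PTK2",)),
        PathwayNode(
            "PI3K",
            ("PIK3CA", "PIK3CB", "PIK3CD", "PIK3R1", "PIK3R2", "PIK3R3"),
        ),
        PathwayNode("PDPK1", ("PDPK1",)),
        PathwayNode("PTEN", ("PTEN",)),
        PathwayNode("AKT3", ("AKT3",)),
        PathwayNode("TSC", ("TSC1", "TSC2")),
        PathwayNode("nCRTC2", ("nCRTC2",)),
        PathwayNode("FOXO3", ("FOXO3",)),
        PathwayNode("BAD", ("BAD",)),
        PathwayNode("GSK3B", ("GSK3B",)),
    ]
    edges = [
        ("IRS1", "PI3K"),
        ("PTK2", "PI3K"),
        ("PI3K", "PDPK1"),
        ("PTEN", "PDPK1"),
        ("PDPK1", "AKT3"),
        ("AKT3", "TSC"),
        ("AKT3", "FOXO3"),
        ("AKT3", "BAD"),
        ("AKT3", "GSK3B"),
        ("AKT3", "nCRTC2"),
    ]
    return PathwayNetwork("pi3k_akt", nodes, edges)


def mapk() -> PathwayNetwork:
    """MAPK signaling reduced to the RAS activation core (11 nodes, 20 genes).

    RAF1 and BRAF sit in distinct branches (classic RAS->RAF1 and
    RAP1->BRAF) and are therefore kept as separate singleton nodes rather
    than one RAF family node.
    """
    nodes = [
        PathwayNode("SOS", ("SOS1", "SOS2")),
        PathwayNode("RAS", ("MRAS", "HRAS", "KRAS", "NRAS")),
        PathwayNode("RASA2", ("RASA2",)),
        PathwayNode("NF1", ("NF1",)),
        PathwayNode("RAPGEF2", ("RAPGEF2",)),
        PathwayNode("PRKC", ("PRKCA", "PRKCB", "PRKCG")),
        PathwayNode("RAF1", ("RAF1",)),
        PathwayNode("BRAF", ("BRAF",)),
        PathwayNode("MAP2K", ("MAP2K1", "MAP2K2")),
        PathwayNode("MAPK", ("MAPK1", "MAPK3")),
        PathwayNode("RAP1", ("RAP1A", "RAP1B")),
    ]
    edges = [
        ("SOS", "RAS"),
        ("NF1", "RAS"),
        ("RASA2", "RAS"),
        ("RAPGEF2", "RAP1"),
        ("RAP1", "BRAF"),
        ("PRKC", "RAF1"),
        ("RAS", "RAF1"),
        ("RAS", "BRAF"),
        ("RAF1", "MAP2K"),
        ("BRAF", "MAP2K"),
        ("MAP2K", "MAPK"),
    ]
    return PathwayNetwork("mapk", nodes, edges)


def neurotrophin() -> PathwayNetwork:
    """Neurotrophin signaling reduced to the p75/JNK branch (9 nodes, 11 genes)."""
    nodes = [
        PathwayNode("NGFR", ("NGFR",)),
        PathwayNode("TRAF6", ("TRAF6",)),
        PathwayNode("RAC1", ("RAC1",)),
        PathwayNode("MAP3K1", ("MAP3K1",)),
        PathwayNode("MAP2K7", ("MAP2K7",)),
        PathwayNode("JNK", ("MAP8", "MAP9", "MAP10")),
        PathwayNode("TP53", ("TP53",)),
        PathwayNode("TP73", ("TP73",)),
        PathwayNode("JUN", ("JUN",)),
    ]
    edges = [
        ("NGFR", "TRAF6"),
        ("TRAF6", "RAC1"),
        ("RAC1", "MAP3K1"),
        ("MAP3K1", "MAP2K7"),
        ("MAP2K7", "JNK"),
        ("JNK", "JUN"),
        ("JNK", "TP53"),
        ("JNK", "TP73"),
    ]
    return PathwayNetwork("neurotrophin", nodes, edges)


def focal_adhesion() -> PathwayNetwork:
    """Focal adhesion reduced to the FAK/CRK scaffold (11 nodes, 27 genes)."""
    nodes = [
        PathwayNode("PTK2", ("PTK2",)),
        PathwayNode("PTEN", ("PTEN",)),
        PathwayNode("BCAR1", ("BCAR1",)),
        PathwayNode("CRK", ("CRK", "CRKL")),
        PathwayNode("DOCK1", ("DOCK1",)),
        PathwayNode(
            "PI3K",
            ("PIK3CA", "PIK3CB", "PIK3CD", "PIK3R1", "PIK3R2", "PIK3R3"),
        ),
        PathwayNode("VAV", ("VAV1", "VAV2", "VAV3")),
        PathwayNode("RAC", ("RAC1", "RAC2", "RAC3")),
        PathwayNode("PAK", ("PAK1", "PAK2", "PAK3", "PAK4", "PAK5", "PAK6")),
        PathwayNode("RAPGEF1", ("RAPGEF1",)),
        PathwayNode("RAP1", ("RAP1A", "RAP1B")),
    ]
    edges = [
        ("PTEN", "PTK2"),
        ("PTK2", "BCAR1"),
        ("BCAR1", "CRK"),
        ("CRK", "DOCK1"),
        ("CRK", "RAPGEF1"),
        ("DOCK1", "RAC"),
        ("RAPGEF1", "RAP1"),
        ("PTK2", "PI3K"),
        ("PI3K", "VAV"),
        ("VAV", "RAC"),
        ("RAC", "PAK"),
    ]
    return PathwayNetwork("focal_adhesion", nodes, edges)


def bundled_networks() -> dict[str, PathwayNetwork]:
    """All five bundled pathway networks, keyed by name."""
    nets = [serine_biosynthesis(), pi3k_akt(), mapk(), neurotrophin(), focal_adhesion()]
    return {n.name: n for n in nets}
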