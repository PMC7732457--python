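"""Regenerate the bundled default atlas metadata table.

The table pairs the 180 HCP-MMP1 cortical parcel names (per hemisphere) and
19 subcortical structures (9 per hemisphere + brain stem) with lobe and
large-scale-network assignments. The lobe/network columns are configuration:
they encode one defensible coordinate-based assignment, and users can supply
their own table instead.

Usage: python scripts/build_atlas_metadata.py
Writes src/connanomaly/data/atlas_hcpmmp1_subcortical.tsv
"""
from __future__ import annotations

import csv
import pathlib

# HCP-MMP1 parcel names in atlas index order (1..180).
MMP_PARCELS = [
    "V1", "MST", "V6", "V2", "V3", "V4", "V8", "4", "3b", "FEF",
    "PEF", "55b", "V3A", "RSC", "POS2", "V7", "IPS1", "FFC", "V3B", "LO1",
    "LO2", "PIT", "MT", "A1", "PSL", "SFL", "PCV", "STV", "7Pm", "7m",
    "POS1", "23d", "v23ab", "d23ab", "31pv", "5m", "5mv", "23c", "5L", "24dd",
    "24dv", "7AL", "SCEF", "6ma", "7Am", "7PL", "7PC", "LIPv", "VIP", "MIP",
    "1", "2", "3a", "6d", "6mp", "6v", "p24pr", "33pr", "a24pr", "p32pr",
    "a24", "d32", "8BM", "p32", "10r", "47m", "8Av", "8Ad", "9m", "8BL",
    "9p", "10d", "8C", "44", "45", "47l", "a47r", "6r", "IFJa", "IFJp",
    "IFSp", "IFSa", "p9-46v", "46", "a9-46v", "9-46d", "9a", "10v", "a10p", "10pp",
    "11l", "13l", "OFC", "47s", "LIPd", "6a", "i6-8", "s6-8", "43", "OP4",
    "OP1", "OP2-3", "52", "RI", "PFcm", "PoI2", "TA2", "FOP4", "MI", "Pir",
    "AVI", "AAIC", "FOP1", "FOP3", "FOP2", "PFt", "AIP", "EC", "PreS", "H",
    "ProS", "PeEc", "STGa", "PBelt", "A5", "PHA1", "PHA3", "STSda", "STSdp", "STSvp",
    "TGd", "TE1a", "TE1p", "TE2a", "TF", "TE2p", "PHT", "PH", "TPOJ1", "TPOJ2",
    "TPOJ3", "DVT", "PGp", "IP2", "IP1", "IP0", "PFop", "PF", "PFm", "PGi",
    "PGs", "V6A", "VMV1", "VMV3", "PHA2", "V4t", "FST", "V3CD", "LO3", "VMV2",
    "31pd", "31a", "VVC", "25", "s32", "pOFC", "PoI1", "Ig", "FOP5", "p10p",
    "p47r", "TGv", "MBelt", "LBelt", "A4", "STSva", "TE1m", "PI", "a32pr", "p24",
]

# Subcortical structures per hemisphere (FreeSurfer-style segmentation) + brain stem.
SUBCORTICAL = [
    ("thalamus", "thalamus", "Thalamus"),
    ("caudate", "basal_ganglia", "Basal ganglia"),
    ("putamen", "basal_ganglia", "Basal ganglia"),
    ("pallidum", "basal_ganglia", "Basal ganglia"),
    ("hippocampus", "hippocampus", "Limbic"),
    ("amygdala", "amygdala", "Limbic"),
    ("accumbens", "accumbens", "Basal ganglia"),
    ("ventralDC", "diencephalon", "Diencephalon"),
    ("cerebellum", "cerebellum", "Cerebellum"),
]

LOBES = {
    "occipital": {
        "V1", "V2", "V3", "V4", "V6", "V7", "V8", "V3A", "V3B", "V3CD",
        "V4t", "V6A", "VMV1", "VMV2", "VMV3", "VVC", "LO1", "LO2", "LO3",
        "PIT", "MT", "MST", "FST", "FFC", "ProS", "DVT", "IPS1",
    },
    # Cingulate plus adjoining medial frontal/parietal wall: anterior-to-
    # posterior cingulate belt and precuneal midline areas.
    "cingulate": {
        "p24", "a24", "p24pr", "a24pr", "33pr", "p32pr", "a32pr", "24dd",
        "24dv", "d32", "p32", "s32", "25", "23d", "23c", "v23ab", "d23ab",
        "31pv", "31pd", "31a", "7m", "7Pm", "PCV", "POS1", "POS2", "RSC",
        "SCEF",
    },
    "orbitofrontal": {
        "OFC", "pOFC", "11l", "13l", "47m", "47s", "47l", "a47r", "p47r",
        "a10p", "p10p", "10pp", "10v", "10r",
    },
    "frontal": {
        "4", "6d", "6mp", "6v", "6r", "6a", "6ma", "FEF", "PEF", "55b",
        "8BM", "8BL", "8Av", "8Ad", "8C", "9m", "9p", "9a", "10d", "44",
        "45", "46", "a9-46v", "p9-46v", "9-46d", "IFJa", "IFJp", "IFSa",
        "IFSp", "SFL", "i6-8", "s6-8", "43",
    },
    "parietal": {
        "1", "2", "3a", "3b", "5m", "5mv", "5L", "7AL", "7Am", "7PC", "7PL",
        "LIPv", "LIPd", "VIP", "MIP", "AIP", "IP0", "IP1", "IP2", "PF",
        "PFm", "PFt", "PFop", "PFcm", "PGi", "PGs", "PGp", "OP1", "OP4",
        "OP2-3", "STV", "PSL",
    },
    "temporal": {
        "A1", "A4", "A5", "LBelt", "MBelt", "PBelt", "RI", "TA2", "PI",
        "STGa", "STSda", "STSdp", "STSva", "STSvp", "TE1a", "TE1m", "TE1p",
        "TE2a", "TE2p", "TGd", "TGv", "TF", "PHT", "PH", "PHA1", "PHA2",
        "PHA3", "EC", "PreS", "PeEc", "H", "TPOJ1", "TPOJ2", "TPOJ3",
    },
    "insula": {
        "52", "Ig", "MI", "AVI", "AAIC", "Pir", "PoI1", "PoI2", "FOP1",
        "FOP2", "FOP3", "FOP4", "FOP5",
    },
}

NETWORKS = {
    "Visual": {
        "V1", "V2", "V3", "V4", "V6", "V7", "V8", "V3A", "V3B", "V3CD",
        "V4t", "V6A", "VMV1", "VMV2", "VMV3", "VVC", "LO1", "LO2", "LO3",
        "PIT", "MT", "MST", "FST", "FFC", "ProS", "DVT",
    },
    "Auditory": {"A1", "A4", "A5", "LBelt", "MBelt", "PBelt", "RI", "TA2", "PI"},
    "Language": {"STSda", "STSdp", "STSva", "STSvp", "STGa", "PSL", "STV", "44", "45", "55b"},
    "Sensorimotor": {
        "4", "3a", "3b", "1", "2", "5m", "5mv", "5L", "24dd", "24dv",
        "6d", "6mp", "6v", "SFL", "43", "OP4", "OP1",
    },
    "DMN": {
        "p24", "a24", "33pr", "d32", "p32", "10r", "10v", "10d", "7m",
        "23d", "23c", "v23ab", "d23ab", "31pv", "31pd", "31a", "PCV",
        "POS1", "POS2", "RSC", "PGi", "PGs", "PFm",
    },
    "Salience": {"a24pr", "p24pr", "p32pr", "a32pr", "25", "SCEF", "FOP5"},
    "DMPFC": {"8BM", "s32", "9a", "9m"},
    "DLPFC": {
        "8BL", "8Av", "8Ad", "8C", "9p", "46", "a9-46v", "p9-46v",
        "9-46d", "IFJa", "IFJp", "IFSa", "IFSp", "i6-8", "s6-8",
    },
    "Orbitofrontal": {
        "OFC", "pOFC", "11l", "13l", "47m", "47s", "47l", "a47r", "p47r",
        "a10p", "p10p", "10pp",
    },
    "Dorsal Premotor": {"6a", "6ma", "6r"},
    "DAN": {"FEF", "PEF", "LIPv", "LIPd", "VIP", "MIP", "AIP", "7PC", "IPS1"},
    "SPL": {"7PL", "7Pm", "7AL", "7Am"},
    "VAN": {"TPOJ1", "TPOJ2", "TPOJ3", "PFop"},
    "Lateral parietal": {"PF", "PFt", "PFcm", "OP2-3", "IP0", "IP1", "IP2", "PGp"},
    "Insula": {"52", "Ig", "MI", "AVI", "AAIC", "Pir", "PoI1", "PoI2",
               "FOP1", "FOP2", "FOP3", "FOP4"},
    "Limbic": {"EC", "PreS", "PeEc", "TF", "PHA1", "PHA2", "PHA3", "H",
               "TGd", "TGv"},
    "Temporal": {"TE1a", "TE1m", "TE1p", "TE2a", "TE2p", "PHT", "PH"},
}


def _lookup(tables: dict[str, set[str]], parcel: str) -> str:
    hits = [label for label, members in tables.items() if parcel in members]
    if len(hits) != 1:
        raise ValueError(f"parcel {parcel!r} matched {hits!r}")
    return hits[0]


def main() -> None:
    assert len(MMP_PARCELS) == 180, len(MMP_PARCELS)
    assert len(set(MMP_PARCELS)) == 180
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "connanomaly" / "data"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for hemi, prefix in (("left", "L_"), ("right", "R_")):
        for parcel in MMP_PARCELS:
            rows.append({
                "name": prefix + parcel,
                "hemisphere": hemi,
                "kind": "cortical",
                "subcortical_class": "none",
                "lobe": _lookup(LOBES, parcel),
                "network": _lookup(NETWORKS, parcel),
            })
    for hemi, prefix in (("left", "L_"), ("right", "R_")):
        for stem, klass, network in SUBCORTICAL:
            rows.append({
                "name": prefix + stem,
                "hemisphere": hemi,
                "kind": "subcortical",
                "subcortical_class": klass,
                "lobe": "subcortical",
                "network": network,
            })
    rows.append({
        "name": "Brain stem",
        "hemisphere": "midline",
        "kind": "subcortical",
        "subcortical_class": "brainstem",
        "lobe": "subcortical",
        "network": "Brainstem",
    })
    assert len(rows) == 379
    path = out / "atlas_hcpmmp1_subcortical.tsv"
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    print(f"wrote {path} ({len(rows)} regions)")


if __name__ == "__main__":
    main()
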