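"""File formats: VCF for genotypes (read via cyvcf2), TSV for panels,
haplotype maps and cohorts, JSON for truth/manifest sidecars.

Per-sample genotype keys are (family_id, individual_id); VCF sample
columns encode them as ``family__individual``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .carriers import HaplotypeMap
from .filtering import ReferencePanel, VariantRecord
from .pedigree import Pedigree

__all__ = [
    "write_vcf", "read_vcf", "write_panel", "read_panel",
    "write_hap_maps", "read_hap_maps", "write_cohort", "read_cohort",
    "write_json", "read_json",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
_SAMPLE_SEP = "__"


def _fmt_ann(pred_score: tuple[str | None, float | None]) -> str:
    pred, score = pred_score
    if pred is None:
        return "NA"
    return f"{pred}:{score}"


def _parse_ann(text: str | None) -> tuple[str | None, float | None]:
    if text in (None, "NA", ""):
        return (None, None)
    pred, score = text.split(":")
    return pred, float(score)


def write_vcf(variants: list[VariantRecord], path: str | Path) -> None:
    samples = sorted({k for v in variants for k in v.genotypes})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({v.chrom for v in variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT pred:score">\n')
        fh.write('##INFO=<ID=PP2,Number=1,Type=String,Description="PolyPhen2 pred:score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO", "FORMAT"] + [_SAMPLE_SEP.join(s) for s in samples]
        fh.write("\t".join(cols) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            info = (f"GENE={v.gene};CSQ={v.consequence};"
                    f"SIFT={_fmt_ann(v.sift)};PP2={_fmt_ann(v.polyphen)}")
            gts = [_GT[v.genotypes.get(s)] for s in samples]
            fh.write("\t".join([v.chrom, str(v.pos), v.vid, v.ref, v.alt,
                                ".", "PASS", info, "GT"] + gts) + "\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    keys = [tuple(s.split(_SAMPLE_SEP, 1)) for s in vcf.samples]
    out = []
    for rec in vcf:
        genotypes: dict[tuple[str, str], int | None] = {}
        for key, gt in zip(keys, rec.gt_types):
            # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            genotypes[key] = {0: 0, 1: 1, 3: 2, 2: None}[gt]
        out.append(VariantRecord(
            chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
            gene=rec.INFO.get("GENE", ""),
            consequence=rec.INFO.get("CSQ", "other"),
            sift=_parse_ann(rec.INFO.get("SIFT")),
            polyphen=_parse_ann(rec.INFO.get("PP2")),
            genotypes=genotypes))
    return out


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    rows = [{"variant_id": vid, "population": pop, "af": af}
            for vid, by_pop in sorted(panel.freqs.items())
            for pop, af in sorted(by_pop.items())]
    df = pd.DataFrame(rows, columns=["variant_id", "population", "af"])
    with open(path, "w") as fh:
        fh.write(f"#populations={','.join(panel.populations)}\n")
        fh.write(f"#european={','.join(panel.european_populations)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_panel(path: str | Path) -> ReferencePanel:
    pops: list[str] = []
    eur: tuple[str, ...] = ()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key == "populations":
                pops = val.split(",")
            elif key == "european":
                eur = tuple(val.split(","))
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["variant_id", "population", "af"], header=0,
                     dtype={"variant_id": str, "population": str})
    freqs: dict[str, dict[str, float]] = {}
    for _, r in df.iterrows():
        freqs.setdefault(r["variant_id"], {})[r["population"]] = float(r["af"])
    return ReferencePanel(populations=pops or sorted(df["population"].unique()),
                          freqs=freqs,
                          european_populations=eur or ("ESP_EA", "KG_EUR"))


def write_hap_maps(hap_maps: dict[str, dict[str, HaplotypeMap]],
                   path: str | Path) -> None:
    rows = []
    for vid, fams in sorted(hap_maps.items()):
        for fam, hm in sorted(fams.items()):
            for iid, (l1, l2) in sorted(hm.labels.items()):
                rows.append({"variant_id": vid, "family_id": fam,
                             "individual_id": iid, "label_1": l1,
                             "label_2": l2})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hap_maps(path: str | Path,
                  peds: list[Pedigree]) -> dict[str, dict[str, HaplotypeMap]]:
    rosters = {p.family_id: sorted(m.id for m in p.affected_men())
               for p in peds}
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, dict[str, HaplotypeMap]] = {}
    for (vid, fam), grp in df.groupby(["variant_id", "family_id"], sort=True):
        labels = {r["individual_id"]: (r["label_1"], r["label_2"])
                  for _, r in grp.iterrows()}
        out.setdefault(vid, {})[fam] = HaplotypeMap(
            fam, labels, affected_roster=rosters.get(fam, []))
    return out


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _default(o):
    import numpy as np

    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
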