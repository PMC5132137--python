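"""File formats: VCF with per-sample dosages, phenotype TSV, dosage tables.

Genotypes travel as VCF 4.2 with a ``DS`` FORMAT field holding the imputed
dosage of the ALT (counted) allele and an ``R2`` INFO field with the
imputation quality; phenotypes as a tab-delimited table with ``NA`` as the
missing sentinel. Reading uses pysam; writing emits plain text so files stay
diffable and deterministic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .genetics import VariantSpec

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "read_dosage_table",
    "PHENOTYPE_COLUMNS",
]

# canonical phenotype-table schema (documented in the README)
PHENOTYPE_COLUMNS = [
    "sample_id", "study", "is_case", "coffee_cups", "tea_cups",
    "tnm_stage", "seer_stage", "gleason", "entry_age", "vital_status",
    "cause_of_death", "exit_age", "smoking",
    "pc1", "pc2", "pc3", "pc4", "pc5", "pc6", "pc7", "pc8",
]

_STRING_COLS = {"sample_id", "study", "tnm_stage", "seer_stage",
                "vital_status", "cause_of_death", "smoking"}


def write_vcf(dosages: pd.DataFrame, specs: Sequence[VariantSpec],
              imputation_r2: dict, path) -> Path:
    """Write per-sample ALT-allele dosages as a VCF with a DS FORMAT field.

    ``dosages``: index = sample ids, one column per rsid (NaN → ``.``).
    """
    path = Path(path)
    samples = list(dosages.index.astype(str))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=coffeemr",
        '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation r-squared">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description='
        '"Imputed dosage of the ALT allele (0-2)">',
    ]
    lines += [f"##contig=<ID={spec.chrom}>" for spec in
              sorted(specs, key=lambda s: (s.chrom, s.pos))]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for spec in sorted(specs, key=lambda s: (s.chrom, s.pos)):
        vals = dosages[spec.rsid].to_numpy(dtype=float)
        fields = [("." if np.isnan(v) else f"{v:.4f}") for v in vals]
        lines.append("\t".join([
            spec.chrom, str(spec.pos), spec.rsid, spec.other_allele,
            spec.counted_allele, ".", "PASS",
            f"R2={imputation_r2[spec.rsid]:.4f}", "DS", *fields]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path, specs: Sequence[VariantSpec] | None = None):
    """Read DS dosages; returns (DataFrame samples × rsid, {rsid: R2}).

    When ``specs`` are given, REF/ALT in the file are checked against the
    expected counted/other alleles.
    """
    by_rsid = {s.rsid: s for s in specs} if specs else {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        data, r2 = {}, {}
        for rec in vf:
            rsid = rec.id
            if by_rsid:
                spec = by_rsid.get(rsid)
                if spec is None:
                    continue
                if rec.ref != spec.other_allele or rec.alts[0] != spec.counted_allele:
                    raise ValueError(
                        f"{rsid}: file alleles {rec.ref}/{rec.alts[0]} do not match "
                        f"expected {spec.other_allele}/{spec.counted_allele}")
            vals = []
            for s in samples:
                ds = rec.samples[s].get("DS")
                if isinstance(ds, tuple):
                    ds = ds[0] if ds else None
                # DS is written at 4-decimal precision but stored as float32
                # by the VCF layer; round back so round trips are exact
                vals.append(np.nan if ds is None else round(float(ds), 4))
            data[rsid] = vals
            r2[rsid] = float(rec.info.get("R2", 1.0))
    df = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    if by_rsid:
        missing = set(by_rsid) - set(df.columns)
        if missing:
            raise ValueError(f"variants absent from VCF: {sorted(missing)}")
        df = df[[s.rsid for s in specs]]
    return df, r2


def read_dosage_table(path):
    """Read a 3-column (sample, rsid, dosage) table into samples × rsid."""
    tab = pd.read_csv(path, sep=None, engine="python")
    tab.columns = [c.lower() for c in tab.columns]
    need = {"sample", "rsid", "dosage"}
    if not need.issubset(tab.columns):
        raise ValueError(f"dosage table needs columns {sorted(need)}")
    wide = tab.pivot(index="sample", columns="rsid", values="dosage")
    wide.index.name = "sample_id"
    wide.columns.name = None
    return wide.astype(float)


def write_phenotypes(table: pd.DataFrame, path) -> Path:
    """Write the phenotype table as TSV with NA for missing values."""
    path = Path(path)
    cols = [c for c in PHENOTYPE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    out = table[cols + extra].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV written by :func:`write_phenotypes`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={c: "string" for c in _STRING_COLS})
    for c in _STRING_COLS & set(df.columns):
        df[c] = df[c].astype(object).where(df[c].notna(), np.nan)
    if "is_case" in df.columns:
        df["is_case"] = df["is_case"].astype(int)
    return df
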