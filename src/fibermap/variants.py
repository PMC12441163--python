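"""Variant-set container and VCF 4.2 round-tripping (via pysam)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = ["Variant", "VariantSet"]

_COLUMNS = ["chrom", "pos", "ref", "alt", "var_class"]
_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class Variant:
    """One sequence-level difference attributed to a bulk.

    Identity for set operations is ``(chrom, pos, ref, alt)``; the class
    (SNP vs indel, anchored-string representation) rides along.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    var_class: str = "SNP"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not (_ALPHABET >= set(self.ref) and _ALPHABET >= set(self.alt)):
            raise ValueError("alleles must be over {A,C,G,T}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class VariantSet:
    """A set of called variants with contig metadata.

    Backed by a DataFrame with columns ``chrom, pos, ref, alt, var_class``
    (plus optional ``origin``). Membership is keyed on
    ``(chrom, pos, ref, alt)``; multi-allelic records are split into one
    entry per alternate allele at VCF read time.
    """

    def __init__(self, df: pd.DataFrame, contigs: dict[str, int] | None = None):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        self.df = df.reset_index(drop=True)
        self.contigs = dict(contigs or {})
        if self.contigs:
            used = set(self.df["chrom"].unique())
            undeclared = used - set(self.contigs)
            if undeclared:
                raise ValueError(f"variants on undeclared contigs: {sorted(undeclared)}")

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> pd.Index:
        d = self.df
        return pd.MultiIndex.from_arrays(
            [d["chrom"], d["pos"], d["ref"], d["alt"]], names=["chrom", "pos", "ref", "alt"]
        )

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Variant(row.chrom, int(row.pos), row.ref, row.alt, row.var_class)

    @classmethod
    def from_variants(cls, variants, contigs: dict[str, int] | None = None) -> "VariantSet":
        rows = [(v.chrom, v.pos, v.ref, v.alt, v.var_class) for v in variants]
        return cls(pd.DataFrame(rows, columns=_COLUMNS), contigs=contigs)

    # ------------------------------------------------------------------ VCF
    def to_vcf(self, path, sample: str = "BULK") -> None:
        """Write as single-sample VCF 4.2; every record is called 1/1."""
        header = pysam.VariantHeader()
        for name, length in self.contigs.items():
            header.contigs.add(name, length=length)
        header.info.add("VARCLASS", 1, "String", "Variant class (SNP or indel)")
        header.info.add("ORIGIN", 1, "String", "Bulk of origin after subtraction")
        header.formats.add("GT", 1, "String", "Genotype")
        header.add_sample(sample)
        has_origin = "origin" in self.df.columns
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for row in self.df.itertuples(index=False):
                rec = vf.new_record(
                    contig=row.chrom,
                    start=int(row.pos) - 1,
                    alleles=(row.ref, row.alt),
                )
                rec.info["VARCLASS"] = row.var_class
                if has_origin:
                    rec.info["ORIGIN"] = row.origin
                rec.samples[sample]["GT"] = (1, 1)
                vf.write(rec)

    @classmethod
    def from_vcf(cls, path, sample: str | None = None) -> "VariantSet":
        """Read a VCF; multi-allelic records split per alternate allele.

        With ``sample`` given (multi-sample bulk VCF), only records whose
        genotype for that sample includes the alternate allele are kept.
        """
        rows = []
        with pysam.VariantFile(str(path)) as vf:
            contigs = {name: c.length for name, c in vf.header.contigs.items()}
            for rec in vf:
                alts = rec.alts or ()
                for ai, alt in enumerate(alts, start=1):
                    if sample is not None:
                        gt = rec.samples[sample].get("GT")
                        if gt is None or ai not in [g for g in gt if g is not None]:
                            continue
                    var_class = "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "indel"
                    vc = rec.info.get("VARCLASS")
                    origin = rec.info.get("ORIGIN")
                    rows.append(
                        (rec.contig, rec.pos, rec.ref, alt, vc or var_class, origin)
                    )
        df = pd.DataFrame(rows, columns=_COLUMNS + ["origin"])
        if df["origin"].isna().all():
            df = df.drop(columns="origin")
        return cls(df, contigs=contigs)
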