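"""Carrier screening: find cataloged resistance mutations in VCF call sets.

A call is accepted as a carrier hit only when the record matches the
target's genomic position, ref and alt alleles, carries a PASS filter, and
is annotated on the same transcript on which the mutation is cataloged.
Samples carrying two or more distinct target mutations can be excluded
downstream (compound-mutation ambiguity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = ["GenomicTarget", "CarrierHit", "load_targets", "screen_vcf", "exclude_multicarriers"]


@dataclass(frozen=True)
class GenomicTarget:
    """The genomic coordinates of a cataloged single-nucleotide substitution."""

    mutation_id: str
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    transcript_id: str

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.mutation_id}: only single-nucleotide substitutions")


@dataclass(frozen=True)
class CarrierHit:
    sample_id: str
    mutation_id: str
    vaf: float  # NaN when depths/frequency unavailable

    def __post_init__(self):
        if self.vaf == self.vaf and not 0.0 <= self.vaf <= 1.0:  # NaN passes
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")


def load_targets(path) -> list[GenomicTarget]:
    """Read a target table TSV with columns mutation_id, chromosome,
    position, ref, alt, transcript_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        GenomicTarget(
            row["mutation_id"], str(row["chromosome"]), int(row["position"]),
            row["ref"], row["alt"], row["transcript_id"],
        )
        for _, row in df.iterrows()
    ]


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _strip_version(accession: str) -> str:
    return accession.split(".")[0]


def screen_vcf(
    vcf_path,
    targets: list[GenomicTarget],
    transcript_key: str = "TRANSCRIPT",
    sample_label: str | None = None,
) -> list[CarrierHit]:
    """Scan a VCF (v4.x, plain or bgzipped) for carriers of the targets.

    ``transcript_key`` names the INFO field carrying the annotated
    transcript(s); comma-separated lists are accepted and matched
    version-insensitively. VAF comes from per-sample allele depths
    (alt/(ref+alt)) when present, else from a per-sample AF format field,
    else from an INFO AF field; with none of these the hit carries NaN and
    a warning is logged.

    Multi-sample VCFs attribute hits to each sample whose genotype carries
    the alt allele; for site-only VCFs all hits go to ``sample_label``
    (default: the file stem).
    """
    lookup = {
        (_norm_chrom(t.chromosome), t.position, t.ref, t.alt): t for t in targets
    }
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    default_sample = sample_label or Path(str(vcf_path)).stem

    hits: list[CarrierHit] = []
    for variant in vcf:
        if variant.FILTER is not None:  # cyvcf2: None means PASS
            continue
        for alt in variant.ALT:
            target = lookup.get((_norm_chrom(variant.CHROM), variant.POS, variant.REF, alt))
            if target is None:
                continue
            annotation = variant.INFO.get(transcript_key)
            if annotation is None:
                logger.warning(
                    "record %s:%d lacks %s annotation; skipped",
                    variant.CHROM, variant.POS, transcript_key,
                )
                continue
            annotated = {_strip_version(t.strip()) for t in str(annotation).split(",")}
            if _strip_version(target.transcript_id) not in annotated:
                continue
            if samples:
                ad = _format_or_none(variant, "AD")
                af = _format_or_none(variant, "AF")
                gt_types = variant.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
                for i, sample in enumerate(samples):
                    if gt_types[i] not in (1, 3):
                        continue
                    hits.append(CarrierHit(sample, target.mutation_id,
                                           _sample_vaf(ad, af, i, variant)))
            else:
                hits.append(CarrierHit(default_sample, target.mutation_id,
                                       _site_vaf(variant)))
    return hits


def _format_or_none(variant, key: str):
    try:
        return variant.format(key)
    except KeyError:
        return None


def _sample_vaf(ad, af, i: int, variant) -> float:
    if ad is not None:
        ref_d, alt_d = float(ad[i][0]), float(ad[i][1])
        if ref_d + alt_d > 0:
            return alt_d / (ref_d + alt_d)
    if af is not None:
        return float(af[i][0])
    return _site_vaf(variant)


def _site_vaf(variant) -> float:
    af = variant.INFO.get("AF")
    if af is not None:
        return float(af[0] if isinstance(af, tuple) else af)
    logger.warning("no AD/AF available at %s:%d; VAF missing", variant.CHROM, variant.POS)
    return float("nan")


def exclude_multicarriers(hits: list[CarrierHit]) -> tuple[list[CarrierHit], list[str]]:
    """Remove samples carrying two or more distinct target mutations.

    Returns (retained hits, excluded sample ids). Counts are conserved:
    retained plus the excluded samples' hits equal the input.
    """
    by_sample: dict[str, set[str]] = {}
    for hit in hits:
        by_sample.setdefault(hit.sample_id, set()).add(hit.mutation_id)
    excluded = sorted(s for s, muts in by_sample.items() if len(muts) >= 2)
    if excluded:
        logger.info("excluding multi-carrier samples: %s", ", ".join(excluded))
    retained = [h for h in hits if h.sample_id not in excluded]
    return retained, excluded


def write_carriers(hits: list[CarrierHit], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [h.sample_id for h in hits],
            "mutation_id": [h.mutation_id for h in hits],
            "vaf": [h.vaf for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)
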