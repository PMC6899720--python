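"""Reading and writing VCF v4.2 with GT/GQ/PL/AD genotype fields.

Reading goes through :mod:`cyvcf2`; writing is a small text emitter (one
biallelic or multiallelic SNP per record, 1-based positions).  Phred-scaled
PL triplets are converted to normalized genotype-probability triplets via
``p(g) ∝ 10^(−PL_g/10)``; log10-scaled GL fields via ``p(g) ∝ 10^(GL_g)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:
    from cyvcf2 import VCF as _CyVCF
except ImportError:  # pragma: no cover
    _CyVCF = None


@dataclass
class RawVariantData:
    """Unfiltered per-variant arrays, the input of the filter cascade."""

    samples: np.ndarray      # (N,)
    contig: np.ndarray       # (L,)
    pos: np.ndarray          # (L,) int, 1-based
    qual: np.ndarray         # (L,) float, NaN if missing
    n_alt: np.ndarray        # (L,) count of ALT alleles
    dosage: np.ndarray       # (L, N) float, NaN missing (biallelic semantics)
    gq: np.ndarray           # (L, N) float, NaN missing
    probs: np.ndarray | None     # (L, N, 3) from PL/GL, NaN triplet if missing
    ref_depth: np.ndarray | None  # (L, N) from AD
    alt_depth: np.ndarray | None

    @property
    def loci(self) -> np.ndarray:
        return np.array([f"{c}:{p}" for c, p in zip(self.contig, self.pos)], dtype=object)

    @property
    def n_loci(self) -> int:
        return len(self.contig)


def phred_to_probs(pl: np.ndarray) -> np.ndarray:
    """Normalized genotype probabilities from phred-scaled likelihoods (…, 3)."""
    pl = np.asarray(pl, dtype=float)
    lik = np.power(10.0, -pl / 10.0)
    return lik / lik.sum(axis=-1, keepdims=True)


def log10gl_to_probs(gl: np.ndarray) -> np.ndarray:
    gl = np.asarray(gl, dtype=float)
    gl = gl - gl.max(axis=-1, keepdims=True)
    lik = np.power(10.0, gl)
    return lik / lik.sum(axis=-1, keepdims=True)


def probs_to_pl(probs: np.ndarray, cap: int = 9999) -> np.ndarray:
    """Phred-scale a probability triplet, rescaled so the best genotype is 0."""
    p = np.clip(np.asarray(probs, dtype=float), 1e-300, None)
    pl = -10.0 * np.log10(p)
    pl = pl - pl.min(axis=-1, keepdims=True)
    return np.minimum(np.rint(pl), cap).astype(int)


def read_vcf(path) -> RawVariantData:
    """Load every record of a VCF into :class:`RawVariantData`."""
    if _CyVCF is None:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files")
    vcf = _CyVCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    n = len(samples)

    contig, pos, qual, n_alt = [], [], [], []
    dosage, gq, probs, ref_d, alt_d = [], [], [], [], []
    any_pl = False
    any_ad = False
    # cyvcf2 gt_types codes: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    gt_map = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        contig.append(v.CHROM)
        pos.append(v.POS)
        qual.append(np.nan if v.QUAL is None else float(v.QUAL))
        n_alt.append(len(v.ALT))
        dosage.append(gt_map[np.asarray(v.gt_types, dtype=int)])
        q = np.asarray(v.gt_quals, dtype=float)
        q[q < 0] = np.nan
        gq.append(q)

        tri = np.full((n, 3), np.nan)
        pl = v.format("PL")
        if pl is not None and pl.shape[1] >= 3:
            pl = pl[:, :3].astype(float)
            ok = np.all((pl >= 0) & (pl < 2 ** 30), axis=1)
            tri[ok] = phred_to_probs(pl[ok])
            any_pl = True
        else:
            gl = v.format("GL")
            if gl is not None and gl.shape[1] >= 3:
                gl = gl[:, :3].astype(float)
                ok = np.all(np.isfinite(gl), axis=1)
                tri[ok] = log10gl_to_probs(gl[ok])
                any_pl = True
        probs.append(tri)

        ad = v.format("AD")
        rd = np.full(n, np.nan)
        altd = np.full(n, np.nan)
        if ad is not None and ad.shape[1] >= 2:
            ad = ad[:, :2].astype(float)
            ok = np.all((ad >= 0) & (ad < 2 ** 30), axis=1)
            rd[ok] = ad[ok, 0]
            altd[ok] = ad[ok, 1]
            any_ad = True
        ref_d.append(rd)
        alt_d.append(altd)

    L = len(contig)
    shape2 = (L, n) if L else (0, n)
    return RawVariantData(
        samples=samples,
        contig=np.array(contig, dtype=object),
        pos=np.array(pos, dtype=int),
        qual=np.array(qual, dtype=float),
        n_alt=np.array(n_alt, dtype=int),
        dosage=np.array(dosage, dtype=float).reshape(shape2),
        gq=np.array(gq, dtype=float).reshape(shape2),
        probs=np.array(probs, dtype=float).reshape(shape2 + (3,)) if any_pl else None,
        ref_depth=np.array(ref_d, dtype=float).reshape(shape2) if any_ad else None,
        alt_depth=np.array(alt_d, dtype=float).reshape(shape2) if any_ad else None,
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, samples, contig, pos, qual, dosage, gq=None, pl=None,
              ref_depth=None, alt_depth=None, ref=None, alt=None) -> None:
    """Emit a VCF v4.2 text file.

    ``dosage`` (L, N): alt-allele dosage, NaN written as ``./.``.
    ``pl`` (L, N, 3) ints; ``ref_depth``/``alt_depth`` (L, N) for AD.
    ``alt`` entries may be comma-joined strings for multiallelic records.
    """
    L = len(contig)
    ref = ["A"] * L if ref is None else list(ref)
    alt = ["C"] * L if alt is None else list(alt)
    fmt_keys = ["GT"]
    if gq is not None:
        fmt_keys.append("GQ")
    if pl is not None:
        fmt_keys.append("PL")
    if ref_depth is not None:
        fmt_keys.append("AD")
    fmt = ":".join(fmt_keys)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hostrace\n")
        for c in dict.fromkeys(contig):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if pl is not None:
            fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,'
                     'Description="Phred-scaled genotype likelihoods">\n')
        if ref_depth is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic read depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in samples) + "\n")
        for i in range(L):
            q = "." if qual is None or not np.isfinite(qual[i]) else f"{qual[i]:g}"
            cells = []
            for j in range(len(samples)):
                d = dosage[i, j]
                parts = ["./." if not np.isfinite(d) else _GT[int(d)]]
                if gq is not None:
                    g = gq[i, j]
                    parts.append("." if not np.isfinite(g) else str(int(round(g))))
                if pl is not None:
                    parts.append("." if not np.isfinite(d)
                                 else ",".join(str(int(x)) for x in pl[i, j]))
                if ref_depth is not None:
                    rd, ad_ = ref_depth[i, j], alt_depth[i, j]
                    parts.append("." if not (np.isfinite(rd) and np.isfinite(ad_))
                                 else f"{int(rd)},{int(ad_)}")
                cells.append(":".join(parts))
            fh.write(f"{contig[i]}\t{int(pos[i])}\t.\t{ref[i]}\t{alt[i]}\t{q}\tPASS\t.\t{fmt}\t"
                     + "\t".join(cells) + "\n")
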