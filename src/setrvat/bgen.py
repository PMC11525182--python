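"""Minimal BGEN v1.2 (layout 2, unphased diploid biallelic, uncompressed,
16-bit probabilities) writer and reader.

Only the subset of the published BGEN specification needed to round-trip
gene pseudovariants is implemented: sample identifiers are stored in the
sample block, genotype probability blocks are uncompressed, and every
record is diploid with two alleles.
"""

from __future__ import annotations

import struct

import numpy as np

_MAGIC = b"bgen"


def write_bgen(path: str, probs: np.ndarray, variant_ids: list[str],
               sample_ids: list[str], bits: int = 16) -> None:
    """Write an (n_samples x n_variants x 3) genotype-probability array.

    Probability triples are (hom-alt, het, hom-ref) in the caller's
    convention; they are stored in BGEN genotype order (ref/ref, ref/alt,
    alt/alt) with the final probability implicit.
    """
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    probs = np.asarray(probs, dtype=float)
    n, m, _ = probs.shape
    if m != len(variant_ids) or n != len(sample_ids):
        raise ValueError("probability array does not match id lists")
    scale = (1 << bits) - 1

    with open(path, "wb") as fh:
        # sample identifier block
        sblock = bytearray()
        for sid in sample_ids:
            b = sid.encode()
            sblock += struct.pack("<H", len(b)) + b
        sample_block = struct.pack("<II", 8 + len(sblock), n) + bytes(sblock)
        flags = struct.pack("<I", (0) | (2 << 2) | (1 << 31))  # layout 2, sample ids
        offset = 20 + len(sample_block)
        fh.write(struct.pack("<I", offset))
        fh.write(struct.pack("<III", 20, m, n))  # header length, M, N
        fh.write(_MAGIC)
        fh.write(flags)
        fh.write(sample_block)

        for k, vid in enumerate(variant_ids):
            vb = vid.encode()
            rec = struct.pack("<H", len(vb)) + vb  # variant id
            rec += struct.pack("<H", len(vb)) + vb  # rsid
            chrom = b"PSEUDO"
            rec += struct.pack("<H", len(chrom)) + chrom
            rec += struct.pack("<I", k + 1)  # position
            rec += struct.pack("<H", 2)  # two alleles
            for allele in (b"A", b"B"):
                rec += struct.pack("<I", len(allele)) + allele
            # genotype data (uncompressed)
            data = bytearray()
            data += struct.pack("<I", n)
            data += struct.pack("<H", 2)  # K alleles
            data += struct.pack("<BB", 2, 2)  # min/max ploidy
            data += bytes([2]) * n  # ploidy 2, not missing
            data += struct.pack("<BB", 0, bits)  # unphased, bit depth
            homalt = probs[:, k, 0]
            het = probs[:, k, 1]
            homref = probs[:, k, 2]
            # stored order: P(ref/ref), P(ref/alt); P(alt/alt) implicit
            p1 = np.round(homref * scale).astype(np.uint32)
            p2 = np.round(het * scale).astype(np.uint32)
            fmt = "<H" if bits == 16 else "<B"
            for a, b in zip(p1, p2):
                data += struct.pack(fmt, int(a)) + struct.pack(fmt, int(b))
            rec += struct.pack("<I", len(data)) + bytes(data)
            fh.write(rec)


def read_bgen(path: str):
    """Read a file written by :func:`write_bgen`.

    Returns (probs, variant_ids, sample_ids) with probabilities in the
    (hom-alt, het, hom-ref) convention.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    off = 0
    (first_block,) = struct.unpack_from("<I", buf, off); off += 4
    lh, m, n = struct.unpack_from("<III", buf, off)
    magic = buf[off + 12:off + 16]
    if magic != _MAGIC:
        raise ValueError("not a BGEN file")
    (flags,) = struct.unpack_from("<I", buf, off + 16)
    layout = (flags >> 2) & 0xF
    compression = flags & 0x3
    if layout != 2 or compression != 0:
        raise ValueError("only uncompressed layout-2 BGEN is supported")
    off += lh
    sample_ids = []
    if flags >> 31:
        sb_len, sn = struct.unpack_from("<II", buf, off)
        p = off + 8
        for _ in range(sn):
            (slen,) = struct.unpack_from("<H", buf, p); p += 2
            sample_ids.append(buf[p:p + slen].decode()); p += slen
        off += sb_len
    variant_ids = []
    probs = np.zeros((n, m, 3))
    for k in range(m):
        (l,) = struct.unpack_from("<H", buf, off); off += 2
        variant_ids.append(buf[off:off + l].decode()); off += l
        (l,) = struct.unpack_from("<H", buf, off); off += 2 + l  # rsid
        (l,) = struct.unpack_from("<H", buf, off); off += 2 + l  # chrom
        off += 4  # position
        (n_alleles,) = struct.unpack_from("<H", buf, off); off += 2
        for _ in range(n_alleles):
            (al,) = struct.unpack_from("<I", buf, off); off += 4 + al
        (dlen,) = struct.unpack_from("<I", buf, off); off += 4
        p = off
        off += dlen
        (nn,) = struct.unpack_from("<I", buf, p); p += 4
        p += 2  # K
        p += 2  # min/max ploidy
        p += nn  # ploidy bytes
        phased, bits = struct.unpack_from("<BB", buf, p); p += 2
        if phased:
            raise ValueError("phased data not supported")
        scale = (1 << bits) - 1
        fmt = "<H" if bits == 16 else "<B"
        step = 2 if bits == 16 else 1
        for i in range(nn):
            (v1,) = struct.unpack_from(fmt, buf, p); p += step
            (v2,) = struct.unpack_from(fmt, buf, p); p += step
            homref, het = v1 / scale, v2 / scale
            probs[i, k] = (max(0.0, 1.0 - homref - het), het, homref)
    return probs, variant_ids, sample_ids
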