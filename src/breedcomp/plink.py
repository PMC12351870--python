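"""Read and write PLINK genotype files (.ped/.map and .bed/.bim/.fam).

Dosage counts copies of the A1 allele — the allele in the first allele column
of the ``.map``/``.bim`` file — so a ``.bed`` byte code of ``00`` (homozygous
A1) decodes to dosage 2 and ``11`` (homozygous A2) to 0. Missing calls
(``0 0`` pairs in ``.ped``, code ``01`` in ``.bed``) become ``NaN``.

Only the SNP-major v1.00 binary layout (magic bytes ``0x6c 0x1b 0x01``) is
supported, matching what current PLINK writes by default.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, make_panel

BED_MAGIC = bytes((0x6C, 0x1B, 0x01))

#: 2-bit .bed code -> dosage of A1 (NaN = missing)
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_BED_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


class PlinkFormatError(ValueError):
    """Malformed or mutually inconsistent PLINK files."""


def read_plink(prefix: str | os.PathLike, dialect: str = "bed_bim_fam") -> GenotypeMatrix:
    """Read a PLINK fileset given its path prefix.

    Parameters
    ----------
    prefix : path
        Path without extension; ``prefix.ped``/``prefix.map`` or
        ``prefix.bed``/``prefix.bim``/``prefix.fam`` must exist.
    dialect : {"bed_bim_fam", "ped_map"}
    """
    prefix = Path(prefix)
    if dialect == "ped_map":
        return _read_ped_map(prefix)
    if dialect == "bed_bim_fam":
        return _read_bed(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_plink(g: GenotypeMatrix, prefix: str | os.PathLike, dialect: str = "bed_bim_fam") -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "ped_map":
        _write_ped_map(g, prefix)
    elif dialect == "bed_bim_fam":
        _write_bed(g, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_map(path: Path) -> pd.DataFrame:
    # .map: chrom, snp_id, cM, pos  (no allele columns; alleles recovered
    # from .ped calls, with A1 = the lexically smaller observed allele
    # overridden below when writing our own files)
    rows = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype=str,
    )
    return rows


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    snps = _read_map(map_path)
    m = len(snps)

    samples: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"({m} SNPs), found {len(fields)}"
                )
            samples.append(fields[1])
            alleles = np.array(fields[6:], dtype=object).reshape(m, 2)
            allele_rows.append(alleles)
    if not samples:
        raise PlinkFormatError(f"{ped_path}: no samples")
    calls = np.stack(allele_rows)  # n x m x 2

    # determine the two alleles per SNP from the observed calls
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    dosage = np.full((len(samples), m), np.nan)
    for j in range(m):
        col = calls[:, j, :]
        obs = np.unique(col[col != "0"])
        bad = [a for a in obs if len(a) != 1 or not a.isalpha()]
        if bad:
            line = 1 + int(np.argmax((col == bad[0]).any(axis=1)))
            raise PlinkFormatError(
                f"{ped_path}: unknown allele {bad[0]!r} at SNP "
                f"{snps['snp_id'].iat[j]!r} (sample line {line})"
            )
        if len(obs) > 2:
            raise PlinkFormatError(
                f"{ped_path}: SNP {snps['snp_id'].iat[j]!r} has "
                f"{len(obs)} alleles; only biallelic SNPs are supported"
            )
        # .map carries no allele columns, so A1 must be inferred: the
        # lexically smaller observed allele is A1 (deterministic; the
        # simulator writes A1='A', A2='G' so this is self-consistent).
        # With a single observed allele, treat it as A2: at MAF <= 0.5 an
        # unobserved *counted* allele is the likelier explanation.
        obs = sorted(obs)
        if len(obs) == 0:
            obs = ["A", "G"]  # fully missing SNP; placeholder alleles
        elif len(obs) == 1:
            obs = ["C" if obs[0] == "A" else "A"] + obs
        a1[j], a2[j] = obs[0], obs[1]
        missing = (col == "0").any(axis=1)
        dosage[:, j] = (col == a1[j]).sum(axis=1)
        dosage[missing, j] = np.nan

    panel = make_panel(snps["snp_id"], snps["chrom"], snps["pos"].astype(int), a1, a2)
    return GenotypeMatrix(samples=samples, panel=panel, dosage=dosage)


def _write_ped_map(g: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in g.panel.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(g.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, row in enumerate(g.panel.itertuples(index=False)):
                d = g.dosage[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [row.a1, row.a1]
                elif d == 1:
                    fields += [row.a1, row.a2]
                else:
                    fields += [row.a2, row.a2]
            fh.write(" ".join(fields) + "\n")


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"], dtype=str,
    )
    return bim


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = _read_bim(prefix.with_suffix(".bim"))
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    samples = fam[1].tolist()
    n, m = len(samples), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed: bad magic bytes {raw[:3].hex()} "
            f"(expected SNP-major v1.00, {BED_MAGIC.hex()})"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: size {len(raw)} does not match "
            f"{n} samples x {m} SNPs (expected {expected})"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts) & 0b11  # m x bytes x 4
    codes = codes.reshape(m, -1)[:, :n]
    dosage = _BED_CODE_TO_DOSAGE[codes].T.copy()  # n x m

    panel = make_panel(bim["snp_id"], bim["chrom"], bim["pos"].astype(int), bim["a1"], bim["a2"])
    return GenotypeMatrix(samples=samples, panel=panel, dosage=dosage)


def _write_bed(g: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in g.panel.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in g.samples:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")

    n, m = g.n_samples, g.n_snps
    bytes_per_snp = (n + 3) // 4
    codes = np.full((m, bytes_per_snp * 4), 0b01, dtype=np.uint8)  # pad = missing code
    for value, code in _DOSAGE_TO_BED_CODE.items():
        codes[:, :n][(g.dosage.T == value)] = code
    codes[:, :n][np.isnan(g.dosage.T)] = 0b01
    codes[:, n:] = 0b00  # PLINK pads trailing sample slots with zero bits
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes.reshape(m, bytes_per_snp, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())
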