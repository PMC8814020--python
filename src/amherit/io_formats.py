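"""Readers/writers for PLINK 1 bed/bim/fam, GCTA GRM archives, and run configs.

All writers are deterministic byte-for-byte given identical inputs.  Missing
genotypes are never produced by the simulator but are handled on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import GRM
from .simulator import SimConfig

__all__ = [
    "PlinkDataset",
    "write_plink",
    "read_plink",
    "write_grm",
    "read_grm",
    "load_config",
    "serialize_config",
    "write_manifest",
    "write_phenotype",
    "read_phenotype",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1 bed, SNP-major


def _p(prefix, ext):
    return Path(str(prefix) + ext)

# 2-bit codes, indexed by allele-1 dosage (0, 1, 2); missing is 0b01
_CODE_OF_DOSAGE = np.array([0b11, 0b10, 0b00], dtype=np.uint8)
_DOSAGE_OF_CODE = np.array([2, -1, 1, 0], dtype=np.int8)


@dataclass
class PlinkDataset:
    """In-memory PLINK triplet: allele-1 dosages plus per-SNP/per-sample tables."""

    genotypes: np.ndarray  # (n, p) int8, -1 = missing
    bim: pd.DataFrame  # chrom, snp, cm, bp, a1, a2
    fam: pd.DataFrame  # fid, iid, father, mother, sex, phenotype


def write_plink(genotypes, snp_meta: pd.DataFrame, sample_meta: pd.DataFrame, prefix):
    """Write a bed/bim/fam triplet (PLINK 1, v1.00 SNP-major).

    ``genotypes`` holds allele-1 counts in {0, 1, 2} (or -1/NaN for
    missing).  ``snp_meta`` needs columns chrom, snp, bp (cm, a1, a2
    optional); ``sample_meta`` needs fid, iid (phenotype optional).
    """
    prefix = Path(prefix)
    G = np.asarray(genotypes)
    if np.issubdtype(G.dtype, np.floating):
        G = np.where(np.isnan(G), -1, G).astype(np.int64)
    n, p = G.shape
    if not np.isin(G, [-1, 0, 1, 2]).all():
        raise ValueError("genotype values must be 0/1/2 or missing (-1/NaN)")

    codes = np.where(G >= 0, _CODE_OF_DOSAGE[np.clip(G, 0, 2)], 0b01).astype(np.uint8)
    pad = (-n) % 4
    if pad:
        # trailing slots of the last byte per SNP are zero-filled, per format
        codes = np.vstack([codes, np.zeros((pad, p), dtype=np.uint8)])
    quads = codes.T.reshape(p, -1, 4)
    payload = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(_p(prefix,".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(payload.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": np.asarray(snp_meta["chrom"]),
            "snp": np.asarray(snp_meta["snp"]),
            "cm": np.asarray(snp_meta["cm"]) if "cm" in snp_meta else np.zeros(p),
            "bp": np.asarray(snp_meta["bp"]),
            "a1": np.asarray(snp_meta["a1"]) if "a1" in snp_meta else ["A"] * p,
            "a2": np.asarray(snp_meta["a2"]) if "a2" in snp_meta else ["G"] * p,
        }
    )
    bim.to_csv(_p(prefix,".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": np.asarray(sample_meta["fid"]),
            "iid": np.asarray(sample_meta["iid"]),
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": (
                np.asarray(sample_meta["phenotype"])
                if "phenotype" in sample_meta
                else np.full(n, -9)
            ),
        }
    )
    fam.to_csv(_p(prefix,".fam"), sep="\t", header=False, index=False)


def read_plink(prefix) -> PlinkDataset:
    """Read a PLINK 1 bed/bim/fam triplet into memory."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        _p(prefix,".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(
        _p(prefix,".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
    )
    n, p = len(fam), len(bim)
    raw = Path(_p(prefix,".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{_p(prefix,'.bed')}: bad magic bytes (not PLINK 1 SNP-major)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if len(raw) != expected:
        raise ValueError(
            f"{_p(prefix,'.bed')}: payload is {len(raw)} bytes, expected {expected}"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_snp)
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for s in range(4):
        codes[:, s::4] = (payload >> (2 * s)) & 0b11
    G = _DOSAGE_OF_CODE[codes[:, :n]].T.copy()
    return PlinkDataset(genotypes=G, bim=bim, fam=fam)


def write_grm(grm: GRM, prefix, n_snps_per_pair=None):
    """Write a GCTA GRM archive (.grm.bin / .grm.N.bin / .grm.id).

    Values are the row-major lower triangle (diagonal included) as 4-byte
    little-endian floats; the N file holds per-pair SNP counts in the same
    layout.
    """
    prefix = str(prefix)
    A = np.asarray(getattr(grm, "values", grm), dtype=float)
    n = A.shape[0]
    if not np.allclose(A, A.T, atol=1e-6):
        raise ValueError("GRM must be symmetric")
    tri = A[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix + ".grm.bin")
    if n_snps_per_pair is None:
        n_snps_per_pair = np.full(tri.size, getattr(grm, "m_used", 0) or 0)
    np.asarray(n_snps_per_pair).astype("<f4").tofile(prefix + ".grm.N.bin")
    ids = getattr(grm, "ids", None)
    if ids is None:
        ids = np.arange(n)
    pd.DataFrame({"fid": ids, "iid": ids}).to_csv(
        prefix + ".grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix) -> GRM:
    """Read a GCTA GRM archive back into a dense symmetric matrix."""
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None, names=["fid", "iid"])
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(
            f"GRM bin holds {tri.size} values but id file implies {n * (n + 1) // 2}"
        )
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    A = np.zeros((n, n))
    A[np.tril_indices(n)] = tri
    A = A + np.tril(A, -1).T
    m_used = int(counts.max()) if counts.size else 0
    return GRM(n=n, values=A, m_used=m_used, ids=ids["iid"].to_numpy())


_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(SimConfig)}


def load_config(path) -> SimConfig:
    """Load and validate a flat key-value simulation config.

    Unknown keys and out-of-range values raise with the offending keys
    named; defaults (burn-in 5, 15 AM generations, relatedness cutoff 0.05,
    ...) fill everything except the mandatory master ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    unknown = sorted(set(raw) - set(_CONFIG_FIELDS))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "seed" not in raw:
        raise ValueError("config must specify a master 'seed'")
    try:
        return SimConfig(**raw)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def serialize_config(config: SimConfig) -> dict:
    """Normalized plain-dict form of a config (round-trips through YAML)."""
    return dataclasses.asdict(config)


def write_phenotype(path, fid, iid, values):
    """PLINK-convention phenotype TSV: FID IID PHENO, missing = NA."""
    df = pd.DataFrame({"FID": fid, "IID": iid, "PHENO": values})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.upper() for c in df.columns]
    return df


def write_manifest(path, config: dict, seed, files=()):
    """JSON run manifest: config + hash, master seed, and file checksums."""
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "files": {},
    }
    for f in files:
        f = Path(f)
        if f.exists():
            manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
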