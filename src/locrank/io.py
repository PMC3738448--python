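"""Readers and writers for summary tables, dosage matrices and regions.

Conventions: coordinates are 1-based inclusive; the missing-dosage
sentinel in delimited text is ``NA``; output ranks are 1-based; floats are
written with 6 significant digits; every output file carries the resolved
configuration and package version as ``#``-prefixed header lines.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import RegionSnp, TagSnp

logger = logging.getLogger(__name__)

__all__ = [
    "read_summary_table", "read_dosages", "read_vcf_dosages",
    "select_region", "write_table",
]

_REQUIRED = ["snp_id", "z"]
_OPTIONAL_DEFAULTS = {
    "pos": None, "maf": 0.5, "rho_hat": 1.0, "call_rate": 1.0,
    "tag_corr": 0.0, "joint_call_rate": None,
}


def read_summary_table(path: str | Path, tag_id: str | None = None,
                       min_maf: float = 0.01,
                       ) -> tuple[list[RegionSnp], TagSnp | None]:
    """Read per-SNP summary statistics (TSV) into typed, validated records.

    Required columns: ``snp_id``, ``z``.  Recognized optional columns:
    ``pos``, ``maf``, ``rho_hat``, ``call_rate``, ``tag_corr``,
    ``joint_call_rate``; missing accuracy/call-rate values default to 1
    (perfect genotyping) with a logged warning.  Rows with MAF below
    ``min_maf`` are dropped.  If ``tag_id`` is given, that row becomes the
    :class:`TagSnp` and all records are sign-aligned so the tag's coded
    allele is risk-positive (its Z made positive, correlations flipped
    along with it).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty summary table")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col, default in _OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            if col in ("rho_hat", "call_rate"):
                logger.warning("%s: column %r absent; assuming perfectly "
                               "genotyped SNPs", path, col)
            df[col] = default if default is not None else np.nan
    for col in ("z", "maf", "rho_hat", "call_rate", "tag_corr",
                "joint_call_rate"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2    # header + 1-based
            raise ValueError(
                f"{path}: unparseable numeric in column {col!r}, line {line}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("rho_hat", "call_rate"):
        if df[col].isna().any():
            logger.warning("%s: missing %s values default to 1", path, col)
            df[col] = df[col].fillna(1.0)
    df["joint_call_rate"] = df["joint_call_rate"].fillna(
        df["call_rate"].astype(float))

    n0 = len(df)
    kept = df[df["maf"].fillna(0.5) >= min_maf].copy()
    logger.info("%s: read %d rows, %d after MAF>=%g filter",
                path, n0, len(kept), min_maf)

    tag = None
    sign = 1.0
    if tag_id is not None:
        row = kept[kept["snp_id"] == tag_id]
        if row.empty:
            raise ValueError(f"{path}: tag SNP {tag_id!r} not found")
        r = row.iloc[0]
        sign = 1.0 if r["z"] >= 0 else -1.0
        tag = TagSnp(snp_id=tag_id, t_gobs=float(sign * r["z"]),
                     call_rate_g=float(r["call_rate"]))
        kept = kept[kept["snp_id"] != tag_id]

    snps = []
    for _, r in kept.iterrows():
        snps.append(RegionSnp(
            snp_id=str(r["snp_id"]), t_obs=float(r["z"]),
            maf=float(min(r["maf"], 0.5)) if np.isfinite(r["maf"]) else 0.5,
            rho_hat=float(r["rho_hat"]), call_rate=float(r["call_rate"]),
            tag_corr_obs=float(sign * r["tag_corr"]),
            joint_call_rate=float(min(r["joint_call_rate"], r["call_rate"])),
            position=int(r["pos"]) if np.isfinite(r["pos"]) else None))
    return snps, tag


def read_dosages(path: str | Path, tag_id: str | None = None):
    """Read a dosage matrix TSV (rows = individuals, columns = SNPs).

    ``NA`` marks missing dosages; values must lie in [0, 2].  Returns a
    dict with the matrix, SNP ids, per-SNP call rates, and — when
    ``tag_id`` is given — joint call rates and complete-case genotype
    correlations with the tag.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA", "./."])
    if df.empty:
        raise ValueError(f"{path}: empty dosage matrix")
    g = df.to_numpy(dtype=float)
    if np.nanmin(g) < 0 or np.nanmax(g) > 2:
        raise ValueError(f"{path}: dosages outside [0, 2]")
    ids = list(df.columns)
    obs = ~np.isnan(g)
    out = {"dosages": g, "snp_ids": ids,
           "call_rates": obs.mean(axis=0)}
    if tag_id is not None:
        if tag_id not in ids:
            raise ValueError(f"{path}: tag SNP {tag_id!r} not a column")
        t = ids.index(tag_id)
        joint = (obs & obs[:, [t]]).mean(axis=0)
        corr = np.zeros(len(ids))
        for j in range(len(ids)):
            both = obs[:, j] & obs[:, t]
            if both.sum() > 1 and g[both, j].std() > 0 and g[both, t].std() > 0:
                corr[j] = np.corrcoef(g[both, j], g[both, t])[0, 1]
        corr[t] = 1.0
        out.update(tag_index=t, joint_call_rates=joint, tag_corr=corr)
    return out


def read_vcf_dosages(path: str | Path, tag_id: str | None = None):
    """Read dosages from a VCF's DS field (GT fallback) via cyvcf2."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:   # pragma: no cover
        raise ImportError("reading VCF dosages requires cyvcf2") from exc
    ids, cols = [], []
    for var in VCF(str(path)):
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gts = var.gt_types.astype(float)      # 0,1,2,3(=unknown)
            ds = np.where(gts == 3, np.nan, np.where(gts == 2, 2.0, gts))
        if ds is None:
            raise ValueError(
                f"{path}: variant {vid} has neither DS nor GT; convert the "
                "file to include dosages")
        ids.append(vid)
        cols.append(ds)
    if not cols:
        raise ValueError(f"{path}: no variants read")
    g = np.column_stack(cols)
    df = pd.DataFrame(g, columns=ids)
    import io as _io
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep="NA")
    buf.seek(0)
    tmp = pd.read_csv(buf, sep="\t", na_values=["NA"])
    out = {"dosages": tmp.to_numpy(float), "snp_ids": ids,
           "call_rates": (~np.isnan(g)).mean(axis=0)}
    if tag_id is not None:
        full = read_dosages_from_arrays(g, ids, tag_id)
        out.update(full)
    return out


def read_dosages_from_arrays(g: np.ndarray, ids: list[str], tag_id: str):
    """Tag-referenced call rates/correlations for an in-memory matrix."""
    obs = ~np.isnan(g)
    if tag_id not in ids:
        raise ValueError(f"tag SNP {tag_id!r} not present")
    t = ids.index(tag_id)
    joint = (obs & obs[:, [t]]).mean(axis=0)
    corr = np.zeros(len(ids))
    for j in range(len(ids)):
        both = obs[:, j] & obs[:, t]
        if both.sum() > 1 and g[both, j].std() > 0 and g[both, t].std() > 0:
            corr[j] = np.corrcoef(g[both, j], g[both, t])[0, 1]
    corr[t] = 1.0
    return {"tag_index": t, "joint_call_rates": joint, "tag_corr": corr}


def select_region(snps: Sequence[RegionSnp], index_snp: str,
                  ld_r2: dict[str, float], r2_threshold: float = 0.2,
                  ) -> list[RegionSnp]:
    """Subset SNPs in LD with the index SNP (r^2 above threshold).

    ``ld_r2`` maps snp_id to squared correlation with the index SNP; the
    index SNP itself is always retained.
    """
    ids = {s.snp_id for s in snps}
    if index_snp not in ids:
        raise ValueError(f"index SNP {index_snp!r} absent from the table")
    missing = ids - set(ld_r2) - {index_snp}
    if missing:
        raise ValueError(
            f"LD matrix does not cover SNP(s): {sorted(missing)[:5]}")
    out = [s for s in snps
           if s.snp_id == index_snp or ld_r2[s.snp_id] > r2_threshold]
    logger.info("select_region: %d of %d SNPs kept at r2 > %g",
                len(out), len(snps), r2_threshold)
    return out


def write_table(df: pd.DataFrame, path: str | Path,
                config: dict | None = None) -> None:
    """Write a TSV with a resolved-config comment header, 6 sig. digits."""
    from . import __version__
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# locrank {__version__}\n")
        for k, v in (config or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g",
                  na_rep="NA")
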