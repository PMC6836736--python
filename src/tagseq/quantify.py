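"""Abundance quantification and standard-curve statistics.

For tag counting, one read represents one transcript molecule regardless of
transcript length, so transcripts-per-million is a plain proportion:

    TPM_tag(i) = 1e6 * c_i / sum_j c_j

Whole-transcript data must be length-normalized first:

    TPM_length(i) = 1e6 * (c_i / l_i) / sum_j (c_j / l_j)

Standard curves against spike-ins of known concentration are summarized by
r' = Pearson correlation of log10(expected abundance) with log10(count + 1);
the +1 accommodates zero counts at the low end of the dilution series.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

AVOGADRO = 6.02214076e23

log = logging.getLogger(__name__)


class QuantifyError(ValueError):
    pass


def tpm_tag(counts, allow_zero_total: bool = False) -> np.ndarray:
    """Tag-count TPM: proportion of counted reads, scaled to one million."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise QuantifyError("negative counts")
    total = c.sum()
    if total == 0:
        if allow_zero_total:
            return np.zeros_like(c)
        raise QuantifyError("all-zero count column")
    return 1e6 * c / total


def tpm_length(counts, lengths, allow_zero_total: bool = False) -> np.ndarray:
    """Length-normalized TPM for whole-transcript data."""
    c = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if l.shape != c.shape:
        raise QuantifyError("counts and lengths are not aligned")
    if (l <= 0).any():
        raise QuantifyError("transcript lengths must be positive")
    return tpm_tag(c / l, allow_zero_total=allow_zero_total)


def tpm_table(counts: pd.DataFrame, allow_zero_total: bool = False) -> pd.DataFrame:
    """Column-wise tag TPM for a genes x samples count table."""
    return counts.apply(lambda col: tpm_tag(col.to_numpy(),
                                            allow_zero_total=allow_zero_total))


def r_prime(abundance, counts) -> float:
    """Standard-curve statistic: corr(log10 A, log10(C + 1)).

    Zero- or negative-abundance reference entries are excluded (their log is
    undefined); the number excluded is logged.  Zero counts are allowed.
    """
    a = np.asarray(abundance, dtype=float)
    c = np.asarray(counts, dtype=float)
    if a.shape != c.shape:
        raise QuantifyError("abundance and counts are not aligned")
    keep = a > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("r_prime: excluded %d zero-abundance entries", n_excluded)
    a, c = a[keep], c[keep]
    if len(a) < 3:
        raise QuantifyError(f"need at least 3 positive-abundance pairs, have {len(a)}")
    x = np.log10(a)
    y = np.log10(c + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise QuantifyError("zero variance in a log-transformed variable")
    return float(np.corrcoef(x, y)[0, 1])


def spearman_corr(x, y) -> float:
    """Rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise QuantifyError("need at least 3 pairs")
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        raise QuantifyError("zero rank variance")
    return float(rho)


def capture_efficiency(nonduplicate_reads: float, input_molecules: float) -> float:
    """Fraction of input molecules represented by a distinct sequenced read.

    Meaningful when the library is sequenced to completion, i.e. every
    distinct molecule has been seen at least once.
    """
    if input_molecules <= 0:
        raise QuantifyError("input molecule count must be positive")
    if nonduplicate_reads < 0:
        raise QuantifyError("nonduplicate read count must be nonnegative")
    return nonduplicate_reads / input_molecules


def capture_efficiency_percent(nonduplicate_reads: float,
                               input_molecules: float) -> int:
    """Capture efficiency as a percentage rounded to the nearest integer."""
    frac = capture_efficiency(nonduplicate_reads, input_molecules)
    return int(np.floor(frac * 100 + 0.5))


def molecules_from_moles(amount_mol: float) -> int:
    """Convert an amount of substance to a molecule count (Avogadro scaling)."""
    if amount_mol < 0:
        raise QuantifyError("negative amount of substance")
    return int(round(amount_mol * AVOGADRO))


def load_abundance_table(
    path: str,
    mix: Optional[str] = None,
    dilution: float = 1.0,
    volume_ul: float = 1.0,
) -> Dict[str, float]:
    """Read an expected-abundance table.

    Two layouts are supported:
    * two columns ``(id, expected_copies)`` — used directly;
    * spike-in layout ``(id, subgroup, mix1_attomol_ul, mix2_attomol_ul)``
      — requires ``mix`` ("mix1"/"mix2"); expected copies are computed as
      attomol/uL x volume x dilution x 1e-18 x Avogadro.
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "expected_molecules" in cols or "expected_copies" in cols:
        value_col = "expected_molecules" if "expected_molecules" in cols else "expected_copies"
        return dict(zip(df[cols[0]], df[value_col].astype(float) * dilution))
    mix_cols = [c for c in cols if "attomol" in c or c.startswith("mix")]
    if not mix_cols:
        raise QuantifyError(f"unrecognized abundance table layout: columns {cols}")
    if mix is None:
        raise QuantifyError("spike-in layout requires a mix selector")
    matches = [c for c in mix_cols if mix.lower() in c]
    if not matches:
        raise QuantifyError(f"mix {mix!r} not found among columns {mix_cols}")
    attomol = df[matches[0]].astype(float)
    copies = attomol * volume_ul * dilution * 1e-18 * AVOGADRO
    return dict(zip(df[cols[0]], copies))
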