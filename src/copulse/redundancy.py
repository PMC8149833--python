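"""Target-gene redundancy classification from genotype fold changes.

For each shared target the stress/non-stress expression fold change is
measured in three genotypes: wild type (both paralogs pulse together),
*msn2* (Msn4-only pulse) and *msn4* (Msn2-only pulse).  A target is
*redundant* when the sum of its single-mutant fold changes exceeds the
wild-type fold change — each paralog alone recapitulates the activation —
and *nonredundant* otherwise.  Both decision boundaries are strict, per the
rule's wording (">1.2" and "higher than").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

GENOTYPE_COLUMNS = ("fc_wt", "fc_msn2", "fc_msn4")


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in GENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fold-change table missing columns: {missing}")
    vals = table[list(GENOTYPE_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("fold changes must be finite and positive")


def select_targets(table: pd.DataFrame, candidate_ids: list[str],
                   min_fc: float = 1.2) -> pd.DataFrame:
    """Keep candidate targets whose wild-type fold change is strictly > min_fc."""
    if len(candidate_ids) == 0:
        raise ValueError("empty candidate list")
    if table.empty:
        return table.copy()
    _validate(table)
    sel = table[table["gene"].isin(candidate_ids) & (table["fc_wt"] > min_fc)]
    return sel.reset_index(drop=True)


def classify_redundant(record) -> str:
    """'redundant' iff fc_msn2 + fc_msn4 > fc_wt (strict), else 'nonredundant'."""
    return ("redundant"
            if record["fc_msn2"] + record["fc_msn4"] > record["fc_wt"]
            else "nonredundant")


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    _validate(table)
    out = table.copy()
    out["label"] = np.where(
        table["fc_msn2"].to_numpy(float) + table["fc_msn4"].to_numpy(float)
        > table["fc_wt"].to_numpy(float),
        "redundant", "nonredundant")
    return out


def ternary_coordinates(table: pd.DataFrame) -> pd.DataFrame:
    """Sum-normalize the genotype triple so components add to one.

    The centre (1/3, 1/3, 1/3) corresponds to full redundancy (identical
    fold change in all three genotypes); vertices to genotype-exclusive
    activation.
    """
    _validate(table)
    vals = table[list(GENOTYPE_COLUMNS)].to_numpy(dtype=float)
    norm = vals / vals.sum(axis=1, keepdims=True)
    out = pd.DataFrame(norm, columns=[f"t_{c}" for c in GENOTYPE_COLUMNS])
    out.insert(0, "gene", table["gene"].to_numpy())
    return out


def dynamic_range_compare(redundant_fcs: dict[str, np.ndarray],
                          nonredundant_fcs: dict[str, np.ndarray],
                          min_genes: int = 10) -> pd.DataFrame:
    """One-sided K-S comparison of fold-change distributions per stress level.

    Tests, per stress level, whether redundant targets show stochastically
    larger activation fold changes than nonredundant targets (the expected
    signature of temporal-redundancy modulation at high stress).  No
    multiple-testing correction is applied, which is noted in the output.
    """
    rows = []
    for level in redundant_fcs:
        red = np.asarray(redundant_fcs[level], dtype=float)
        non = np.asarray(nonredundant_fcs[level], dtype=float)
        if red.size < min_genes or non.size < min_genes:
            raise ValueError(f"stress level {level!r}: fewer than {min_genes} genes per class")
        # alternative='less': CDF(redundant) below CDF(nonredundant), i.e.
        # redundant stochastically larger
        res = ks_2samp(red, non, alternative="less")
        rows.append({"stress_level": level, "D": float(res.statistic),
                     "p_value": float(res.pvalue),
                     "n_redundant": red.size, "n_nonredundant": non.size,
                     "correction": "none"})
    return pd.DataFrame(rows)
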