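"""Aggregation of per-colony filamentous indices into strain phenotypes.

Covers the downstream bookkeeping between image quantification and bulk
segregant analysis: replicate summaries (mean +/- s.e.m.), per-plate
z-score normalisation (each tray is its own batch), and selection of the
phenotypically extreme segregants that form the high/low sequencing pools.
Only QC-passing colonies enter any statistic.  Model fitting (ANOVA etc.)
is deliberately not reimplemented here; `export_tidy` writes a table any
statistics package can consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TREATMENTS = ("control", "PheOH", "TrpOH")


def _qc_ok(table: pd.DataFrame) -> pd.DataFrame:
    if "qc_status" in table.columns:
        return table[table["qc_status"] == "OK"]
    return table


def summarize(table: pd.DataFrame,
              group_by: list[str] | tuple[str, ...] = ("strain", "treatment"),
              value: str = "filamentous_index") -> pd.DataFrame:
    """Per-group mean, sample sd and standard error of the index.

    Groups with a single replicate get NaN sd/se and ``se_undefined=True``.
    Output is ordered deterministically by the group keys.
    """
    table = _qc_ok(table).dropna(subset=[value])
    if table.empty:
        raise ValueError("no QC-passing rows to summarize")
    group_by = list(group_by)
    g = table.groupby(group_by, sort=True, dropna=False)[value]
    out = g.agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1)).reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["se_undefined"] = out["n"] < 2
    return out


def plate_zscores(table: pd.DataFrame, value: str = "filamentous_index",
                  plate_col: str = "plate") -> pd.DataFrame:
    """Within-plate z-scores: z = (x - plate mean) / plate sample sd.

    Plates with fewer than two QC-passing colonies, or zero spread, are
    flagged (``z_flag``) and their z left missing.  Per valid plate the z
    column has mean 0 and sd 1 to numerical precision.
    """
    table = table.copy()
    table["z"] = np.nan
    table["z_flag"] = ""
    ok = (table["qc_status"] == "OK") if "qc_status" in table.columns \
        else pd.Series(True, index=table.index)
    ok &= table[value].notna()
    for plate, idx in table[ok].groupby(plate_col).groups.items():
        x = table.loc[idx, value].astype(float)
        if len(idx) < 2:
            table.loc[idx, "z_flag"] = "fewer than 2 OK colonies"
            continue
        sd = x.std(ddof=1)
        if sd == 0:
            table.loc[idx, "z_flag"] = "zero spread"
            continue
        table.loc[idx, "z"] = (x - x.mean()) / sd
    return table


def select_pools(summaries: pd.DataFrame, k: int = 22,
                 id_col: str = "strain", mean_col: str = "mean",
                 var_col: str = "variance",
                 epsilon: float = 0.05) -> tuple[list, list]:
    """Pick the k highest- and k lowest-phenotype segregants for bulk pools.

    Ranks by mean (z-scale) phenotype; segregants whose mean lies within
    ``epsilon`` of the k-th rank's are near-ties and are re-ordered by lower
    replicate variance.  Returns disjoint (high ids, low ids).
    """
    if summaries[id_col].duplicated().any():
        raise ValueError("duplicate segregant ids in summaries")
    n = len(summaries)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} segregants, have {n}")

    def _pick(direction: int) -> list:
        # direction +1: highest means; -1: lowest means
        df = summaries.sort_values(
            [mean_col, id_col], ascending=[direction < 0, True],
            kind="mergesort").reset_index(drop=True)
        kth = df[mean_col].iloc[k - 1]
        sure = df[(df[mean_col] - kth) * direction > epsilon]
        border = df[np.abs(df[mean_col] - kth) <= epsilon]
        need = k - len(sure)
        if var_col in df.columns:
            border = border.sort_values(
                [var_col, mean_col, id_col],
                ascending=[True, direction < 0, True], kind="mergesort")
        chosen = pd.concat([sure, border.iloc[:need]])
        return chosen[id_col].tolist()

    high = _pick(+1)
    low = _pick(-1)
    if set(high) & set(low):
        raise ValueError(
            f"high and low pools overlap (k={k} too large for the spread): "
            f"{sorted(set(high) & set(low))}")
    return high, low


def export_tidy(table: pd.DataFrame, path,
                columns: tuple[str, ...] = ("strain", "niche", "population",
                                            "treatment", "assay", "plate",
                                            "well", "filamentous_index",
                                            "qc_status"),
                header_lines: list[str] | None = None) -> None:
    """Write a tidy per-colony CSV with the model-term columns external
    statistics tools expect; missing annotation columns are left blank."""
    out = pd.DataFrame({c: table[c] if c in table.columns else ""
                        for c in columns})
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)
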