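"""AIC computation and ranking of the candidate colonization models.

AIC = 2k - 2 LnL; smaller is better.  The nine constrained hypotheses
compete for the best model; the unconstrained full model is reported
alongside but excluded from the best-vs-runner-up ΔAIC comparison, since
its extra four parameters make it a reference fit rather than a
biogeographic hypothesis.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phylodeme.scenarios import FULL_MODEL_NAME


def aic(lnl: float, k: int) -> float:
    """Akaike Information Criterion 2k - 2 LnL."""
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    return 2.0 * k - 2.0 * lnl


@dataclass
class ModelSelectionTable:
    """Ranked model-selection table.

    ``table`` rows are sorted by AIC ascending with columns
    (scenario, k, LnL, AIC, delta_AIC, rank).  ``rank`` and ``delta_AIC``
    are assigned over the constrained models only; the full model's are
    NaN.  ``delta_AIC`` is measured from the best constrained model.
    """

    table: pd.DataFrame

    @property
    def best(self) -> str:
        return str(self.table.loc[self.table["rank"] == 1, "scenario"].iloc[0])

    @property
    def runner_up_delta(self) -> float:
        """ΔAIC between the best and second-best constrained models."""
        sub = self.table[self.table["rank"] == 2]
        if sub.empty:
            return 0.0
        return float(sub["delta_AIC"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_dict(self) -> dict:
        return {"best": self.best, "runner_up_delta": self.runner_up_delta,
                "rows": self.table.where(pd.notna(self.table), None).to_dict(orient="records")}


def rank_models(rows) -> ModelSelectionTable:
    """Rank (scenario, k, LnL[, AIC]) rows by AIC.

    ``rows`` may be dicts with keys scenario/k/LnL (optionally AIC) or
    (scenario, k, LnL[, AIC]) tuples, or a DataFrame with those columns.
    AIC is computed from (LnL, k) when absent.  Result is order-invariant
    in the input.
    """
    if isinstance(rows, pd.DataFrame):
        recs = rows.to_dict(orient="records")
    else:
        recs = []
        for r in rows:
            if isinstance(r, dict):
                recs.append(dict(r))
            else:
                rec = {"scenario": r[0], "k": r[1], "LnL": r[2]}
                if len(r) > 3:
                    rec["AIC"] = r[3]
                recs.append(rec)
    if not recs:
        raise ValueError("rank_models requires at least one row")
    names = [r["scenario"] for r in recs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate scenario names: {dupes}")
    for r in recs:
        if "AIC" not in r or r["AIC"] is None or (isinstance(r["AIC"], float) and np.isnan(r["AIC"])):
            r["AIC"] = aic(float(r["LnL"]), int(r["k"]))
        r.setdefault("LnL", np.nan)
    df = pd.DataFrame(recs)[["scenario", "k", "LnL", "AIC"]]
    df = df.sort_values(["AIC", "scenario"], kind="mergesort").reset_index(drop=True)
    constrained = df["scenario"] != FULL_MODEL_NAME
    if not constrained.any():
        raise ValueError("at least one constrained model is required")
    best_aic = float(df.loc[constrained, "AIC"].min())
    df["delta_AIC"] = np.where(constrained, df["AIC"] - best_aic, np.nan)
    ranks = np.full(len(df), np.nan)
    ranks[np.where(constrained)[0]] = np.arange(1, int(constrained.sum()) + 1)
    df["rank"] = ranks
    return ModelSelectionTable(df)


def load_printed_table(locus: str | None = None) -> pd.DataFrame:
    """The published model-testing table bundled with the package.

    Columns: locus (coi/hsp70), scenario, k, LnL, AIC (printed values).
    """
    ref = importlib.resources.files("phylodeme") / "data" / "table1.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    if locus is not None:
        df = df[df["locus"] == locus].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"unknown locus {locus!r}")
    return df
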