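"""Downstream statistics: effect sizes, correlations, mediation, puberty analyses.

Uses repeated cross-validation (3 runs) to form always-correct /
always-wrong groups for the misclassification-by-PDS chi-square, computes
score-cognition correlations and the partial mediation of the linked
working-memory score, and reports per-PDS accuracy.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

import sexnet as sx
from sexnet.stats import (
    agreement_groups,
    cohens_d,
    misclassification_chi2,
    partial_mediation,
    per_stratum_accuracy,
    score_correlations,
    summarize,
)
from _cohort import load_study_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--epochs", type=int, default=8)
    ap.add_argument("--runs", type=int, default=3)
    ap.add_argument("--outdir", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = load_study_cohort(args.seed)
    records = cohort.records
    cfg = sx.ModelConfig(grid=cohort.grid, epochs=args.epochs, seed=args.seed)
    preds, reports = sx.repeated_crossvalidate(
        cohort, runs=args.runs, k=5, cfg=cfg, seed=args.seed
    )
    accs = [r.balanced_accuracy for r in reports]
    print(f"balanced accuracy over {args.runs} runs: "
          + ", ".join(f"{100 * a:.1f}%" for a in accs))

    # per-sex effect sizes of the cognitive scores
    nih_cols = [c for c in records.columns if c.startswith("nih_")]
    rows = []
    girls = records["sex"] == 1
    for col in nih_cols:
        d = cohens_d(summarize(records.loc[girls, col]), summarize(records.loc[~girls, col]))
        rows.append({"test": col, "cohens_d": round(d, 3)})
    pd.DataFrame(rows).to_csv(args.outdir / "effect_sizes.csv", index=False)

    # correlations and mediation against the first run's CV scores
    pred = preds[0].set_index("subject_id").loc[records["subject_id"]]
    scores = pred["score"].to_numpy()
    corr = score_correlations(scores, records[nih_cols])
    corr.to_csv(args.outdir / "correlations.csv", index=False)
    med = partial_mediation(
        records["sex"].to_numpy(),
        scores,
        records["nih_list_sorting"].to_numpy(),
        n_perm=10_000,
        seed=args.seed,
    )
    pd.DataFrame([dataclasses.asdict(med)]).to_csv(args.outdir / "mediation.csv", index=False)
    print(
        f"working-memory mediation: p1={med.condition1_p:.4f} p2={med.condition2_p:.4f} "
        f"p3={med.condition3_p:.4f} verdict={'partial mediation' if med.verdict else 'none'}"
    )

    # misclassification by puberty
    good, bad = agreement_groups(preds, records)
    chi = misclassification_chi2(good, bad)
    pd.DataFrame(
        [{"sex": k, "chi2": v["chi2"], "p": v["p"], "dof": v["dof"]} for k, v in chi.items()]
    ).to_csv(args.outdir / "misclassification_chi2.csv", index=False)

    # per-PDS accuracy
    merged = preds[0].merge(records[["subject_id", "pds_level"]], on="subject_id")
    strat = per_stratum_accuracy(merged, stratum="pds_level", min_per_sex=10)
    strat.to_csv(args.outdir / "stratum_accuracy.csv", index=False)
    print(strat.to_string(index=False))


if __name__ == "__main__":
    main()
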