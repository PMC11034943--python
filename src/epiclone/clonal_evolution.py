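"""Mutation dynamics between diagnosis and relapse.

A diagnosis/relapse mutation table (one row per variant per patient, with the
variant allele frequency — VAF — at both timepoints) is classified with the
standard threshold rule: a mutation is *gained* when its VAF moves from below
0.05 at diagnosis to above 0.1 at relapse, *lost* on the reverse move, and
*stable* otherwise. Variants without a quantifiable VAF (FLT3-ITD, NPM1
insertions) are classified from presence/absence calls instead. Patients are
then binned by the classes of their mutations (Stable / Gain / Loss /
GainAndLoss), and relapse-free survival is compared between clonally stable
and unstable patients with Kaplan-Meier / log-rank statistics and an age- and
sex-adjusted Cox proportional-hazards model.

Thresholds are strict inequalities: a VAF of exactly 0.05 or 0.1 can never
trigger a gain or loss call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)

GAIN_LOWER = 0.05  # VAF at the "absent" timepoint must be strictly below this
GAIN_UPPER = 0.10  # VAF at the "present" timepoint must be strictly above this

MUTATION_COLUMNS = [
    "patient_id", "gene", "variant_id", "vaf_dx", "vaf_rel",
    "quantifiable", "present_dx", "present_rel", "tier",
]

BINS = ["Stable", "Gain", "Loss", "GainAndLoss"]


def _is_evaluable(row: pd.Series) -> bool:
    if bool(row.get("quantifiable", True)):
        return pd.notna(row["vaf_dx"]) and pd.notna(row["vaf_rel"])
    return pd.notna(row.get("present_dx")) and pd.notna(row.get("present_rel"))


def filter_evaluable_patients(mutations: pd.DataFrame, drop_tier3: bool = True) -> pd.DataFrame:
    """Restrict a cohort to patients whose every variant can be evaluated at
    both timepoints.

    Tier 3 variants (synonymous / unknown significance) are removed before
    the evaluability check; a patient is kept only if all remaining variants
    carry either both VAFs (quantifiable) or both presence flags.
    """
    if mutations.empty:
        raise ValueError("empty mutation cohort")
    df = mutations.copy()
    if drop_tier3 and "tier" in df.columns:
        df = df[df["tier"].isna() | (df["tier"] != 3)]
    evaluable = df.apply(_is_evaluable, axis=1)
    bad_patients = set(df.loc[~evaluable, "patient_id"])
    kept = df[~df["patient_id"].isin(bad_patients)].reset_index(drop=True)
    return kept


def classify_mutation(
    vaf_dx: float | None = None,
    vaf_rel: float | None = None,
    quantifiable: bool = True,
    present_dx: bool | None = None,
    present_rel: bool | None = None,
) -> str:
    """Classify one mutation as ``gained`` / ``lost`` / ``stable``.

    Quantifiable variants use the VAF threshold rule (strictly below 0.05 at
    one timepoint, strictly above 0.1 at the other); non-quantifiable
    variants use absent/present transitions.
    """
    if quantifiable:
        if vaf_dx is None or vaf_rel is None or pd.isna(vaf_dx) or pd.isna(vaf_rel):
            raise ValueError("quantifiable variant is missing a VAF")
        if vaf_dx < GAIN_LOWER and vaf_rel > GAIN_UPPER:
            return "gained"
        if vaf_dx > GAIN_UPPER and vaf_rel < GAIN_LOWER:
            return "lost"
        return "stable"
    if present_dx is None or present_rel is None:
        raise ValueError("non-quantifiable variant is missing presence calls")
    if not present_dx and present_rel:
        return "gained"
    if present_dx and not present_rel:
        return "lost"
    return "stable"


def classify_mutations(mutations: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification; returns a copy with a ``dynamics`` column."""
    df = mutations.copy()
    quant = df["quantifiable"].fillna(True).astype(bool) if "quantifiable" in df else pd.Series(True, index=df.index)
    dyn = pd.Series("stable", index=df.index, dtype=object)

    q = quant.values
    if q.any():
        vd = pd.to_numeric(df.loc[q, "vaf_dx"], errors="coerce")
        vr = pd.to_numeric(df.loc[q, "vaf_rel"], errors="coerce")
        if vd.isna().any() or vr.isna().any():
            raise ValueError("quantifiable variant is missing a VAF")
        gained = (vd < GAIN_LOWER) & (vr > GAIN_UPPER)
        lost = (vd > GAIN_UPPER) & (vr < GAIN_LOWER)
        dyn.loc[vd.index[gained]] = "gained"
        dyn.loc[vd.index[lost]] = "lost"
    if (~q).any():
        pdx = df.loc[~q, "present_dx"].astype(bool)
        prl = df.loc[~q, "present_rel"].astype(bool)
        dyn.loc[pdx.index[~pdx & prl]] = "gained"
        dyn.loc[pdx.index[pdx & ~prl]] = "lost"
    df["dynamics"] = dyn
    return df


def bin_patient(classes: list[str] | pd.Series) -> str:
    """Map a patient's mutation classes to a clonal bin."""
    classes = list(classes)
    if not classes:
        raise ValueError("patient has no classified mutations")
    has_gain = "gained" in classes
    has_loss = "lost" in classes
    if has_gain and has_loss:
        return "GainAndLoss"
    if has_gain:
        return "Gain"
    if has_loss:
        return "Loss"
    return "Stable"


def bin_patients(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-patient clonal bins and the derived stable/unstable clonality.

    ``clonality`` is ``stable`` only for the Stable bin; any gained or lost
    mutation makes a patient ``unstable``.
    """
    rows = []
    for pid, grp in classified.groupby("patient_id", sort=True):
        b = bin_patient(grp["dynamics"])
        rows.append({"patient_id": pid, "bin": b,
                     "clonality": "stable" if b == "Stable" else "unstable"})
    return pd.DataFrame(rows)


def gene_dynamics_summary(
    classified: pd.DataFrame, min_events: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene tallies of gained/lost/stable mutations.

    Returns ``(full, ternary)``: the full table has raw counts and the
    fraction of patients carrying each gene; the ternary table normalizes
    (gained, lost, stable) counts to fractions summing to 1 and is restricted
    to genes with at least ``min_events`` classified mutations.
    """
    n_patients = classified["patient_id"].nunique()
    tab = (
        classified.groupby("gene")["dynamics"]
        .value_counts().unstack(fill_value=0)
        .reindex(columns=["gained", "lost", "stable"], fill_value=0)
    )
    tab.columns = ["n_gained", "n_lost", "n_stable"]
    tab["n_events"] = tab.sum(axis=1)
    carriers = classified.groupby("gene")["patient_id"].nunique()
    tab["pct_patients_mutated"] = 100.0 * carriers / n_patients
    full = tab.reset_index()

    tern = full[full["n_events"] >= min_events].copy()
    for src, dst in [("n_gained", "frac_gained"), ("n_lost", "frac_lost"),
                     ("n_stable", "frac_stable")]:
        tern[dst] = tern[src] / tern["n_events"]
    return full, tern


def survival_compare(
    bins: pd.DataFrame, clinical: pd.DataFrame,
    time_col: str = "days_to_relapse", event_col: str = "relapse_event",
) -> dict:
    """Compare relapse-free survival between clonally stable and unstable
    patients.

    Returns Kaplan-Meier survival curves per group, the log-rank p value and
    an age/sex-adjusted Cox proportional-hazards fit (Efron tie handling);
    the hazard ratio is for stable vs unstable clonality. Patients with
    missing age or sex are dropped from the adjusted model with a warning.
    """
    df = bins.merge(clinical, on="patient_id")
    df = df[df[time_col].notna() & df[event_col].notna()]
    groups = df.groupby("clonality")
    if df["clonality"].nunique() < 2 or (groups[time_col].count() < 2).any():
        raise ValueError("need at least 2 patients with observed times per group")
    if not df.groupby("clonality")[event_col].any().all():
        raise ValueError("a group is fully censored; log-rank undefined")

    km_curves = {}
    for name, grp in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(grp[time_col], grp[event_col], label=name)
        km_curves[name] = kmf.survival_function_

    stable = df[df["clonality"] == "stable"]
    unstable = df[df["clonality"] == "unstable"]
    lr = logrank_test(stable[time_col], unstable[time_col],
                      stable[event_col], unstable[event_col])

    cox_df = df[["patient_id", time_col, event_col, "clonality", "age", "sex"]].copy()
    n_before = len(cox_df)
    cox_df = cox_df.dropna(subset=["age", "sex"])
    if len(cox_df) < n_before:
        logger.warning("dropped %d patients with missing age/sex from Cox model",
                       n_before - len(cox_df))
    cox_df["stable_clonality"] = (cox_df["clonality"] == "stable").astype(float)
    cox_df["male"] = cox_df["sex"].astype(str).str.upper().isin(["M", "MALE", "1"]).astype(float)
    cph = CoxPHFitter()
    cph.fit(cox_df[[time_col, event_col, "stable_clonality", "age", "male"]],
            duration_col=time_col, event_col=event_col)
    hr = float(np.exp(cph.params_["stable_clonality"]))
    ci = np.exp(cph.confidence_intervals_.loc["stable_clonality"]).tolist()
    return {
        "km_curves": km_curves,
        "logrank_p": float(lr.p_value),
        "cox_hr": hr,
        "cox_ci": [float(ci[0]), float(ci[1])],
        "cox_p": float(cph.summary.loc["stable_clonality", "p"]),
        "n": int(len(df)),
    }


def apply_panel_rules(variants: pd.DataFrame, vaf_threshold: float = 0.05) -> pd.DataFrame:
    """Filter a targeted-sequencing variant table down to major-clone,
    disease-relevant mutations.

    Keeps variants whose average VAF exceeds ``vaf_threshold`` at either
    timepoint; drops Tier 3 variants (missing tier is treated as Tier 3 and
    logged).
    """
    df = variants.copy()
    tier = pd.to_numeric(df.get("tier"), errors="coerce")
    missing = tier.isna()
    if missing.any():
        logger.warning("%d variants without tier annotation treated as Tier 3",
                       int(missing.sum()))
    tier = tier.fillna(3)
    keep_tier = tier != 3
    vaf_ok = (pd.to_numeric(df["vaf_dx"], errors="coerce") > vaf_threshold) | (
        pd.to_numeric(df["vaf_rel"], errors="coerce") > vaf_threshold
    )
    return df[keep_tier & vaf_ok.fillna(False)].reset_index(drop=True)
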