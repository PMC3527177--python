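"""Genotyping-based SNP validation.

A SNP discovered in one parent of an F1 mapping population is validated
by how its Infinium genotypes segregate among the progeny: AB x AB loci
should approximate 1:2:1, AB x homozygous loci 1:1 (a test cross), and a
locus monomorphic in the parents and progeny marks a false-positive
discovery.  Group comparisons use Fisher's exact test, and a logistic
model of (MQS, RMD, FVF) predicts the probability that a discovered SNP
is a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

HET = "AB"
HOMS = ("AA", "BB")
MISSING = "NA"

# published coefficients of the false-positive logistic model:
# log(p/(1-p)) = b0 + b1*MQS + b2*RMD + b3*FVF
DEFAULT_TP_COEFFS = (10.3976899, -0.3077982, 0.07896269, -5.2585503)


@dataclass
class SegregationCall:
    """Classified segregation of one marker in the F1 progeny."""

    marker_id: str
    parent1_gt: str
    parent2_gt: str
    progeny_counts: tuple[int, int, int]  # (nAA, nAB, nBB)
    expected_class: str  # ratio_1_2_1 | ratio_1_1 | monomorphic | unscorable
    chi2: float = float("nan")
    pvalue: float = float("nan")


def classify_segregation(
    parent1: str,
    parent2: str,
    progeny_counts: tuple[int, int, int],
    alpha: float = 0.05,
    marker_id: str = "",
    max_inconsistent_fraction: float = 0.05,
) -> SegregationCall:
    """Classify a marker's progeny segregation against its Mendelian expectation.

    AB x AB tests the three classes against 1:2:1 (chi-square, 2 df);
    AB x homozygote collapses to carrier/non-carrier and tests 1:1 (1 df);
    identical homozygous parents with a single progeny class are
    monomorphic.  Progeny in a Mendelian-impossible class are tolerated
    up to ``max_inconsistent_fraction`` (genotyping error) and dropped
    from the test; beyond that the marker is unscorable, as are markers
    with missing parents or no progeny.
    """
    nAA, nAB, nBB = (int(c) for c in progeny_counts)
    if min(nAA, nAB, nBB) < 0:
        raise ValueError("negative progeny counts")
    counts = {"AA": nAA, "AB": nAB, "BB": nBB}
    total = nAA + nAB + nBB

    def unscorable() -> SegregationCall:
        return SegregationCall(marker_id, parent1, parent2, (nAA, nAB, nBB), "unscorable")

    if parent1 not in ("AA", "AB", "BB") or parent2 not in ("AA", "AB", "BB") or total == 0:
        return unscorable()

    def tolerate(impossible: list[str]) -> bool:
        bad = sum(counts[c] for c in impossible)
        return bad <= max_inconsistent_fraction * total

    if parent1 == HET and parent2 == HET:
        obs = np.array([nAA, nAB, nBB], dtype=float)
        chi2, p = stats.chisquare(obs, f_exp=obs.sum() * np.array([0.25, 0.5, 0.25]))
        return SegregationCall(
            marker_id, parent1, parent2, (nAA, nAB, nBB), "ratio_1_2_1", float(chi2), float(p)
        )

    if HET in (parent1, parent2) and (parent1 in HOMS or parent2 in HOMS):
        hom = parent1 if parent1 in HOMS else parent2
        impossible = "BB" if hom == "AA" else "AA"
        if not tolerate([impossible]):
            return unscorable()
        obs = np.array([counts[hom], counts[HET]], dtype=float)  # non-carrier, carrier
        if obs.sum() == 0:
            return unscorable()
        chi2, p = stats.chisquare(obs)
        return SegregationCall(
            marker_id, parent1, parent2, (nAA, nAB, nBB), "ratio_1_1", float(chi2), float(p)
        )

    # both parents homozygous
    if parent1 == parent2:
        expected = parent1
        impossible = [c for c in ("AA", "AB", "BB") if c != expected]
    else:  # AA x BB -> all AB, still no segregation
        expected = HET
        impossible = [c for c in ("AA", "AB", "BB") if c != expected]
    if not tolerate(impossible):
        return unscorable()
    return SegregationCall(
        marker_id, parent1, parent2, (nAA, nAB, nBB), "monomorphic", 0.0, 1.0
    )


def progeny_counts(calls: pd.Series, exclude: tuple[str, ...] = ()) -> tuple[int, int, int]:
    """Tally (nAA, nAB, nBB) from a marker's genotype column, skipping NA."""
    sub = calls.drop(index=list(exclude), errors="ignore")
    vc = sub.value_counts()
    return (int(vc.get("AA", 0)), int(vc.get("AB", 0)), int(vc.get("BB", 0)))


def label_true_false(segregation: SegregationCall, discovery_parent: str = "parent1") -> str:
    """Label the discovered SNP true/false from the segregation evidence.

    The discovery is validated only if the parent in which the SNP was
    discovered is heterozygous and the progeny segregate; a monomorphic
    locus, or a segregating locus at which the discovery parent is
    homozygous, refutes the discovery.
    """
    gt = segregation.parent1_gt if discovery_parent == "parent1" else segregation.parent2_gt
    cls = segregation.expected_class
    if cls == "unscorable":
        return "unscorable"
    if cls == "monomorphic":
        return "false_positive"
    if gt == HET:
        return "true_positive"
    if gt in HOMS:
        return "false_positive"
    return "unscorable"


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell counts")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class TPModel:
    """Logistic model of the false-positive probability of a discovered SNP."""

    b0: float = DEFAULT_TP_COEFFS[0]
    b1: float = DEFAULT_TP_COEFFS[1]  # MQS
    b2: float = DEFAULT_TP_COEFFS[2]  # RMD
    b3: float = DEFAULT_TP_COEFFS[3]  # FVF
    stderr: tuple[float, float, float, float] | None = None

    def log_odds(self, mqs: float, rmd: float, fvf: float) -> float:
        return self.b0 + self.b1 * mqs + self.b2 * rmd + self.b3 * fvf

    def predict(self, mqs: float, rmd: float, fvf: float) -> float:
        return float(expit(self.log_odds(mqs, rmd, fvf)))


def tp_logit_predict(
    mqs: float, rmd: float, fvf: float, model: TPModel | None = None
) -> tuple[float, str]:
    """Evaluate the logistic model; predicted false-positive when p_false > 0.5."""
    model = model or TPModel()
    p_false = model.predict(mqs, rmd, fvf)
    return p_false, ("false_positive" if p_false > 0.5 else "true_positive")


def fit_tp_logit(records) -> tuple[TPModel, dict]:
    """Fit the false-positive logistic model by maximum likelihood.

    ``records`` is a DataFrame (or convertible) with columns
    mqs, rmd, fvf and a boolean/0-1 ``is_false`` response.  Returns the
    fitted model and a report with standard errors and the training-set
    confusion/accuracy at the 0.5 threshold.
    """
    import statsmodels.api as sm

    df = pd.DataFrame(records)
    required = {"mqs", "rmd", "fvf", "is_false"}
    if not required <= set(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if len(df) < 50:
        raise ValueError(f"need >= 50 labeled records, got {len(df)}")
    y = df["is_false"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes (true and false positives) must be present")
    X = sm.add_constant(df[["mqs", "rmd", "fvf"]].astype(float))
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # includes perfect separation
        raise ValueError(f"logistic fit failed (possible perfect separation): {exc}") from exc
    if np.any(~np.isfinite(res.bse)) or np.any(res.bse > 1e4):
        raise ValueError("logistic fit degenerate: unbounded standard errors "
                         "(perfect separation?)")
    b = res.params.to_numpy()
    model = TPModel(*(float(v) for v in b), stderr=tuple(float(v) for v in res.bse))
    p = res.predict(X)
    pred_false = p > 0.5
    actual = y.astype(bool)
    tp_acc = float(np.mean(~pred_false[~actual])) if (~actual).any() else float("nan")
    fp_acc = float(np.mean(pred_false[actual])) if actual.any() else float("nan")
    report = {
        "n": int(len(df)),
        "accuracy": float(np.mean(pred_false == actual)),
        "accuracy_true_positive": tp_acc,
        "accuracy_false_positive": fp_acc,
        "llf": float(res.llf),
    }
    return model, report


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded half-up in decimal, as printed in reports.

    Decimal arithmetic avoids float artifacts at the rounding boundary
    (5163/6000 is exactly 86.05% and must print 86.1, not 86.0).
    """
    from decimal import ROUND_HALF_UP, Decimal

    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    q = Decimal(1).scaleb(-digits)
    val = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


def validation_summary(labels, groups=None) -> dict:
    """Summarise validation outcomes, overall and by annotation group.

    ``labels`` is an iterable of {true_positive, false_positive,
    unscorable}; ``groups`` (optional, same length) assigns each SNP to
    genic/nongenic.  Rates are percentages over the scored
    (non-unscorable) SNPs; a Fisher exact test probes group x outcome
    association when two groups are present.
    """
    labels = list(labels)
    out: dict = {"n": len(labels)}
    if not labels:
        return out
    scored = [l for l in labels if l != "unscorable"]
    n_true = sum(l == "true_positive" for l in scored)
    n_false = sum(l == "false_positive" for l in scored)
    out.update(
        n_scored=len(scored),
        n_true_positive=n_true,
        n_false_positive=n_false,
        true_positive_rate=percent(n_true, len(scored)) if scored else float("nan"),
        false_positive_rate=percent(n_false, len(scored)) if scored else float("nan"),
    )
    if groups is not None:
        groups = list(groups)
        by_group: dict[str, dict] = {}
        table = []
        for g in sorted(set(groups)):
            gl = [l for l, gg in zip(labels, groups) if gg == g and l != "unscorable"]
            nt = sum(l == "true_positive" for l in gl)
            nf = sum(l == "false_positive" for l in gl)
            by_group[g] = {
                "n_scored": len(gl),
                "n_true_positive": nt,
                "n_false_positive": nf,
                "true_positive_rate": percent(nt, len(gl)) if gl else float("nan"),
            }
            table.append((nf, nt))
        out["by_group"] = by_group
        if len(table) == 2 and sum(table[0]) + sum(table[1]) > 0:
            out["fisher_p"] = fisher_exact_2x2(table[0][0], table[1][0], table[0][1], table[1][1])
    return out
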