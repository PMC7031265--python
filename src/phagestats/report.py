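"""Study-report driver: recompute the published tables from first principles.

``run_study_tables`` regenerates the method-comparison study's headline
numbers from the packaged observed counts — MPN points and Jarvis CIs per
volume, two-proportion comparisons between methods, the detection-limit
Poisson rates and the accuracy/specificity bootstrap — and lays each beside
the printed value. Cells where the recomputation disagrees with print (the
ISO 10 µL MPN point; the specificity, whose published procedure is not
recoverable) are flagged, never silently matched.

Every number is emitted as a ``{"raw": <float>, "display": <str>}`` pair;
display rounding is half-away-from-zero at the study's printed precision
(MPN 2 d.p., rates 4 d.p., percentages 2 d.p.).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Any

from . import __version__
from .fixture import reference_study
from .mpn import mpn_interval
from .poisson import AliquotSeries, expected_positive_count
from .validation import (
    bootstrap_accuracy_specificity,
    estimate_method_lambda,
    two_proportion_test,
)

__all__ = ["display_round", "run_study_tables"]


def display_round(value: float, ndigits: int) -> str:
    """Half-away-from-zero decimal rounding, as the study tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _num(value: float | None, ndigits: int) -> dict[str, Any] | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return {"raw": float(value), "display": display_round(value, ndigits)}


def _mpn_cell(label: str, volume: float, n: int, x: int) -> dict[str, Any]:
    est = mpn_interval(AliquotSeries(label, volume, n, x))
    if not est.computable:
        return {"computable": False}
    return {
        "computable": True,
        "point": _num(est.point, 2),
        "ci_low": _num(est.ci_low, 2),
        "ci_high": _num(est.ci_high, 2),
    }


def run_study_tables(seed: int | None = 0, runs: int = 10_000) -> dict[str, Any]:
    """Recompute the study's tables; deterministic for a fixed seed."""
    study = reference_study()
    report: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "runs": runs,
        "sections": {},
    }

    # -- section 1: MPN + Jarvis CI per volume, recomputed vs printed -----
    mpn_rows = []
    for row in study.enumeration:
        entry: dict[str, Any] = {"volume_ul": row.volume_ul, "n": row.n}
        for method, x, printed in (
            ("iso", row.iso_positive, (row.iso_mpn, row.iso_mpn_lo, row.iso_mpn_hi)),
            ("blue", row.blue_positive, (row.blue_mpn, row.blue_mpn_lo, row.blue_mpn_hi)),
        ):
            cell = _mpn_cell(method, row.volume_ul, row.n, x)
            cell["printed"] = {
                "point": printed[0], "ci_low": printed[1], "ci_high": printed[2],
            }
            flags = []
            if cell["computable"] and printed[0] is not None:
                for key, want in zip(("point", "ci_low", "ci_high"), printed):
                    got = cell[key]["display"]
                    if float(got) != want:
                        flags.append(
                            f"{key}: recomputed {got} vs printed {want}"
                        )
            cell["discrepancies"] = flags
            entry[method] = cell
        mpn_rows.append(entry)
    report["sections"]["mpn"] = mpn_rows

    # -- section 2: positive-percentage comparison with two-proportion p --
    prop_rows = []
    for prow in study.proportions:
        erow = study.enumeration_row(prow.volume_ul)
        stat, p = two_proportion_test(
            erow.iso_positive, erow.n, erow.blue_positive, erow.n
        )
        prop_rows.append(
            {
                "volume_ul": prow.volume_ul,
                "n": prow.n,
                "theoretical_pct": _num(prow.theoretical_pct, 2),
                "iso_pct": _num(100 * erow.iso_positive / erow.n, 2),
                "blue_pct": _num(100 * erow.blue_positive / erow.n, 2),
                "iso_vs_blue_chi2": _num(stat, 4),
                "iso_vs_blue_p": _num(p, 4),
                "printed_wilcoxon_p": prow.wilcoxon_p,
            }
        )
    report["sections"]["proportions"] = prop_rows

    # -- section 3: detection-limit rates and validation bootstrap --------
    dl = study.detection_limit
    iso10 = AliquotSeries("ISO-DAL", 10.0, dl.n, dl.iso_positive)
    blue10 = AliquotSeries("Bluephage", 10.0, dl.n, dl.blue_positive)
    row25 = study.enumeration_row(25.0)
    blue25 = AliquotSeries("Bluephage", 25.0, row25.n, row25.blue_positive)

    lam_iso = estimate_method_lambda(iso10)
    lam_blue = estimate_method_lambda(blue10)

    # simulation rates come from the detection-limit fractions (15/42 at
    # 10 µL, 13/18 at 25 µL); references are the ISO-observed positives
    refs = [study.enumeration_row(10.0).iso_positive, row25.iso_positive]
    result = bootstrap_accuracy_specificity(
        sim_series=[iso10, blue25],
        ref_positives=refs,
        runs=runs,
        seed=seed,
    )
    val: dict[str, Any] = {
        "lambda_iso_10ul": _num(lam_iso.lam, 4),
        "lambda_blue_10ul": _num(lam_blue.lam, 4),
        "expected_positives_10ul": _num(
            expected_positive_count(lam_iso, dl.n), 2
        ),
        "reference_positives": refs,
        "accuracy_pct": _num(result.accuracy_point, 2),
        "accuracy_ci_pct": [_num(result.accuracy_ci[0], 2),
                            _num(result.accuracy_ci[1], 2)],
        "specificity_pct": _num(result.specificity_point, 2),
        "specificity_ci_pct": [_num(result.specificity_ci[0], 2),
                               _num(result.specificity_ci[1], 2)],
        "printed": {
            "accuracy_pct": study.accuracy_pct,
            "accuracy_ci_pct": list(study.accuracy_ci),
            "specificity_pct": study.specificity_pct,
            "specificity_ci_pct": list(study.specificity_ci),
        },
        "discrepancies": [
            "printed specificity (97.78%) and its CI follow an unstated "
            "procedure and are not reproduced by the documented definition",
        ],
        "runs": runs,
        "seed": seed,
    }
    report["sections"]["validation"] = val
    return report
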