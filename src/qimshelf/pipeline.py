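"""End-to-end pipeline: simulated (or loaded) study -> full report document."""

from __future__ import annotations

import numpy as np

from .calibration import fit_line
from .indicators import (
    DEFAULT_LIMITS,
    IndicatorSeries,
    correlation_matrix,
    crossing_day_continuous,
    first_crossing_day,
)
from .pls import fit_pls1, loo_cv, vip_scores
from .protocol import Assessment, QimProtocol, aggregate_panel
from .report import (
    RejectionFinding,
    build_report,
    integrate_shelf_life,
    sensory_rejection_day,
)
from .simulate import SimulationConfig, simulate_study


def analyse_study(
    assessments: list[Assessment],
    indicator_series: list[IndicatorSeries],
    protocol: QimProtocol,
    limits=DEFAULT_LIMITS,
) -> dict:
    """Run every analysis stage on one study and assemble the report."""
    panel = aggregate_panel(assessments, protocol)
    days = [p.storage_day for p in panel]

    fit = fit_line(days, [p.qi_mean for p in panel])
    calibration = {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "residual_sd": fit.residual_sd,
        "n": fit.n,
    }

    names = list(protocol.parameter_names)
    X = np.array([[p.per_parameter_mean[k] for k in names] for p in panel])
    y = np.array(days, dtype=float)
    pls_doc = None
    a_max = min(len(panel) - 2, X.shape[1])
    if a_max >= 1:
        try:
            cv = loo_cv(X, y, a_max)
            model = fit_pls1(X, y, cv["chosen_A"])
            vip = vip_scores(model, names)
            pls_doc = {
                "chosen_A": cv["chosen_A"],
                "rmsecv": cv["per_A_rmsecv"],
                "vip": vip.vip,
                "selected": vip.selected(),
                "groups": {k: protocol.group_of(k) for k in names},
            }
        except ValueError:
            pls_doc = None

    by_name = {s.name: s for s in indicator_series}
    crossings: dict = {}
    findings = [sensory_rejection_day(panel, protocol)]
    for rule in limits:
        s = by_name.get(rule.indicator)
        if s is None:
            continue
        observed = first_crossing_day(s, rule)
        crossings[rule.indicator] = {
            "threshold": rule.threshold,
            "direction": rule.direction.value,
            "observed_day": observed,
            "fitted_day": crossing_day_continuous(s.fit(), rule),
        }
        if rule.rejection:
            findings.append(
                RejectionFinding(
                    criterion=rule.indicator,
                    rejection_day=observed,
                    evidence=f"{rule.direction.value} {rule.threshold} {s.units}",
                )
            )

    corr = None
    try:
        mat = correlation_matrix(panel, indicator_series)
        corr = {
            c: {r: float(mat.loc[r, c]) for r in mat.index} for c in mat.columns
        }
    except ValueError:
        corr = None

    shelf = integrate_shelf_life(findings, days)
    return build_report(
        protocol=protocol,
        calibration=calibration,
        pls=pls_doc,
        crossings=crossings,
        correlations=corr,
        shelf_life=shelf,
    )


def run_pipeline(config: SimulationConfig, protocol: QimProtocol) -> dict:
    """Simulate a study under the given conditions and analyse it."""
    study = simulate_study(config, protocol)
    return analyse_study(
        list(study.assessments), list(study.indicator_series), protocol
    )
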