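"""The study-reproduction report and the end-to-end pipeline runner.

:func:`reproduce_paper` refits the four published descriptor subsets on the
packaged 22-compound training set using the packaged descriptor columns,
evaluates the 7-compound test set, spot-checks the descriptor engine against
the packaged reference values, and compares everything against the published
statistics.

Comparisons are split into *hard* targets — the single-descriptor model's
statistics and the descriptor spot-checks, which reproduce from the packaged
data — and *soft* comparisons that are reported and flagged but never fail
the run, because the packaged reference values they depend on are internally
inconsistent (see ``KNOWN_DISCREPANT_CELLS`` and docs/methods.md): the
multi-descriptor model statistics (the published 4-variable coefficients are
irreconcilable with the published ATS6m column), the reported calculated
LogC column, the published correlation matrix (cohort ambiguity), the
external R²/r_m² values, and the SDEP/SPRESS df conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .corpus import (
    DESCRIPTOR_COLUMNS,
    load_packaged_descriptor_matrix,
    load_packaged_smiles,
    load_packaged_solvents,
    study_frame,
)
from .descriptors import (
    KNOWN_DISCREPANT_CELLS,
    build_descriptor_matrix,
    chi0v_average,
    multiple_path_count,
    ram_index,
    srw_count,
    verify_against_reference,
)
from .graph import MolecularGraph
from .regression import DispersibilityMLR, correlation_matrix
from .selection import GAConfig, exhaustive_select, ga_select
from .synthetic import generate_paperlike_dataset
from .validation import validate_model

#: The published models: descriptor subsets with the reported statistics.
PUBLISHED_MODELS: tuple[dict, ...] = (
    {
        "id": 1,
        "subset": ("SRW09",),
        "R2": 0.548, "Q2": 0.453, "F": 24.249, "s": 0.627,
        "SPRESS": 0.690, "SDEP": 0.674,
        "coefficients": {"SRW09": 0.0020, "intercept": -2.1522},
        "halfwidths": {"SRW09": 0.0008, "intercept": 0.3620},
        "R2_test": 0.830, "rm2_avg": 0.773, "rm2_delta": 0.112,
    },
    {
        "id": 2,
        "subset": ("SRW09", "DipoleZ"),
        "R2": 0.679, "Q2": 0.573, "F": 20.080, "s": 0.543,
        "SPRESS": 0.626, "SDEP": 0.595,
        "coefficients": {"SRW09": 0.0019, "DipoleZ": 0.3809, "intercept": -2.1228},
        "halfwidths": {"SRW09": 0.0007, "DipoleZ": 0.2865, "intercept": 0.3149},
        "R2_test": 0.786, "rm2_avg": 0.717, "rm2_delta": 0.137,
    },
    {
        "id": 3,
        "subset": ("Ram", "piPC05", "DipoleZ"),
        "R2": 0.736, "Q2": 0.601, "F": 16.687, "s": 0.506,
        "SPRESS": 0.621, "SDEP": 0.575,
        "coefficients": {
            "Ram": 0.8389, "piPC05": -0.0209, "DipoleZ": 0.3855, "intercept": -2.3590
        },
        "halfwidths": {
            "Ram": 0.2960, "piPC05": 0.0122, "DipoleZ": 0.2920, "intercept": 0.4189
        },
        "R2_test": 0.813, "rm2_avg": 0.751, "rm2_delta": 0.122,
    },
    {
        "id": 4,
        "subset": ("SRW09", "ATS6m", "X0Av", "DipoleZ"),
        "R2": 0.797, "Q2": 0.666, "F": 16.722, "s": 0.456,
        "SPRESS": 0.585, "SDEP": 0.527,
        "coefficients": {
            "SRW09": 0.0022, "ATS6m": 4.0933, "X0Av": -0.0832,
            "DipoleZ": 0.5488, "intercept": -4.5062,
        },
        "halfwidths": {
            "SRW09": 0.0008, "ATS6m": 3.1813, "X0Av": 0.0857,
            "DipoleZ": 0.2716, "intercept": 1.9741,
        },
        "R2_test": 0.807, "rm2_avg": 0.744, "rm2_delta": 0.125,
    },
)

#: Published correlation matrix (descriptors + reported calculated LogC).
PUBLISHED_CORRELATIONS = pd.DataFrame(
    [
        [1.0, -0.004, -0.002, 0.567, 0.053, 0.427, 0.706],
        [-0.004, 1.0, 0.009, 0.068, -0.112, 0.118, 0.377],
        [-0.002, 0.009, 1.0, 0.631, -0.275, 0.532, -0.037],
        [0.567, 0.068, 0.631, 1.0, 0.075, 0.545, 0.530],
        [0.053, -0.112, -0.275, 0.075, 1.0, 0.042, 0.159],
        [0.427, 0.118, 0.532, 0.545, 0.042, 1.0, 0.276],
        [0.706, 0.377, -0.037, 0.530, 0.159, 0.276, 1.0],
    ],
    index=[*DESCRIPTOR_COLUMNS, "LogC_cal"],
    columns=[*DESCRIPTOR_COLUMNS, "LogC_cal"],
)

#: Descriptor spot-check cells that reproduce exactly from the structures.
SPOT_CHECKS: tuple[dict, ...] = (
    {"descriptor": "X0Av", "compound_id": 28, "expected": 0.521, "tol": 5e-4},
    {"descriptor": "X0Av", "compound_id": 22, "expected": 0.727, "tol": 5e-4},
    {"descriptor": "X0Av", "compound_id": 21, "expected": 0.611, "tol": 5e-4},
    {"descriptor": "Ram", "compound_id": 1, "expected": 3, "tol": 0},
    {"descriptor": "Ram", "compound_id": 26, "expected": 1, "tol": 0},
    {"descriptor": "Ram", "compound_id": 27, "expected": 0, "tol": 0},
    {"descriptor": "piPC05", "compound_id": 26, "expected": 44, "tol": 0},
    {"descriptor": "piPC05", "compound_id": 29, "expected": 50, "tol": 0},
    {"descriptor": "SRW09", "compound_id": 26, "expected": 0, "tol": 0},
)

_SPOT_FUNCS = {
    "X0Av": chi0v_average,
    "Ram": ram_index,
    "piPC05": lambda g: multiple_path_count(g, 5),
    "SRW09": lambda g: srw_count(g, 9),
}


@dataclass(frozen=True)
class Tolerances:
    """Comparison tolerances for the reproduction report."""

    r2: float = 0.01
    q2: float = 0.01
    f: float = 0.5
    coef_rel: float = 0.05  # or the published halfwidth, whichever is larger


@dataclass
class ReproductionReport:
    """Refit-vs-published comparison over the packaged study data."""

    model_rows: pd.DataFrame
    spot_checks: pd.DataFrame
    correlation_train: pd.DataFrame
    correlation_all: pd.DataFrame
    descriptor_discrepancies: object  # DiscrepancyReport
    best_subsets: pd.DataFrame  # exhaustive optimum per size over the packaged pool
    tolerances: Tolerances

    @property
    def hard_rows(self) -> pd.DataFrame:
        return self.model_rows[self.model_rows.hard]

    @property
    def passed(self) -> bool:
        return bool(self.hard_rows["pass"].all() and self.spot_checks["pass"].all())

    def to_text(self) -> str:
        lines = ["Reproduction report", "=" * 19, ""]
        lines.append("Model statistics (refit on the 22 training compounds):")
        show = self.model_rows[
            ["model", "quantity", "refit", "published", "abs_diff", "hard", "pass"]
        ]
        lines.append(show.to_string(index=False))
        lines.append("")
        lines.append("Descriptor spot-checks (computed from structures):")
        lines.append(self.spot_checks.to_string(index=False))
        lines.append("")
        lines.append("Exhaustive best subset per size over the packaged 6-column pool")
        lines.append("(published subsets shown for comparison; agreement not asserted):")
        lines.append(self.best_subsets.to_string(index=False))
        lines.append("")
        lines.append(
            "Soft comparisons above are flagged, never fatal: the published\n"
            "multi-descriptor statistics, external-set statistics, SDEP/SPRESS\n"
            "conventions, the reported calculated LogC column and the published\n"
            "correlation matrix are not reproducible from the packaged reference\n"
            "values (documented known discrepancies)."
        )
        lines.append("")
        lines.append("Descriptor matrix vs packaged reference: "
                     + str(self.descriptor_discrepancies).splitlines()[0])
        lines.append(f"Overall hard-target status: {'PASS' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def _compare(quantity, refit, published, tol, model_id, hard) -> dict:
    diff = abs(refit - published)
    return {
        "model": model_id,
        "quantity": quantity,
        "refit": refit,
        "published": published,
        "abs_diff": diff,
        "tolerance": tol,
        "hard": hard,
        "pass": bool(diff <= tol),
    }


def reproduce_paper(tolerances: Tolerances | None = None) -> ReproductionReport:
    """Refit the four published models and compare every statistic.

    Returns a :class:`ReproductionReport`; ``report.passed`` reflects only
    the hard targets (single-descriptor model statistics and descriptor
    spot-checks).
    """
    tol = tolerances or Tolerances()
    df = study_frame()
    train = df[df.split == "train"]
    test = df[df.split == "test"]
    rows: list[dict] = []
    for spec in PUBLISHED_MODELS:
        mid = spec["id"]
        hard = mid == 1  # multi-descriptor stats are documented soft targets
        res = DispersibilityMLR.from_dataframe(train, "LogC", list(spec["subset"])).fit()
        rows.append(_compare("R2", res.rsquared, spec["R2"], tol.r2, mid, hard))
        rows.append(_compare("Q2", res.loo.q2, spec["Q2"], tol.q2, mid, hard))
        rows.append(_compare("F", res.fvalue, spec["F"], tol.f, mid, hard))
        for name, published_coef in spec["coefficients"].items():
            ctol = max(abs(published_coef) * tol.coef_rel, spec["halfwidths"][name])
            rows.append(
                _compare(f"coef[{name}]", float(res.params[name]), published_coef,
                         ctol, mid, hard)
            )
        # df-convention-sensitive and external statistics: always soft
        rows.append(_compare("s", res.s, spec["s"], tol.r2, mid, False))
        rows.append(_compare("SPRESS", res.loo.spress, spec["SPRESS"], tol.r2, mid, False))
        rows.append(_compare("SDEP", res.loo.sdep, spec["SDEP"], tol.r2, mid, False))
        rep = validate_model(res, test, test["LogC"])
        rows.append(_compare("R2_test", rep.r2_test, spec["R2_test"], tol.r2, mid, False))
        rows.append(_compare("rm2_avg", rep.rm2_average, spec["rm2_avg"], tol.r2, mid, False))
        rows.append(_compare("rm2_delta", rep.rm2_delta, spec["rm2_delta"], tol.r2, mid, False))
    model_rows = pd.DataFrame(rows)

    graphs = {i: MolecularGraph.from_smiles(s) for i, s in load_packaged_smiles().items()}
    spot_rows = []
    for check in SPOT_CHECKS:
        g = graphs[check["compound_id"]]
        value = float(_SPOT_FUNCS[check["descriptor"]](g))
        spot_rows.append(
            {
                "descriptor": check["descriptor"],
                "compound_id": check["compound_id"],
                "computed": round(value, 3),
                "expected": check["expected"],
                "pass": bool(abs(value - check["expected"]) <= check["tol"]),
            }
        )
    spot_checks = pd.DataFrame(spot_rows)

    # correlation comparisons, both candidate cohorts (ambiguity documented)
    records = load_packaged_solvents(with_smiles=False)
    cal = pd.Series({r.id: r.log_conc_calc for r in records}, name="LogC_cal")
    full = load_packaged_descriptor_matrix().data.join(cal)
    corr_all = correlation_matrix(full)
    corr_train = correlation_matrix(full.loc[train.index])

    # exhaustive best subsets over the packaged pool, under both fitness
    # options, next to the published per-size subsets
    published_by_size = {len(m["subset"]): m["subset"] for m in PUBLISHED_MODELS}
    subset_rows = []
    pool = train[list(DESCRIPTOR_COLUMNS)]
    for fitness in ("r2", "q2"):
        best = exhaustive_select(pool, train["LogC"], max_vars=4, fitness=fitness)
        for size, cand in sorted(best.items()):
            subset_rows.append(
                {
                    "fitness": fitness,
                    "size": size,
                    "best_subset": "+".join(cand.subset),
                    "best_fitness": round(cand.fitness, 4),
                    "published_subset": "+".join(sorted(published_by_size[size])),
                }
            )
    best_subsets = pd.DataFrame(subset_rows)

    reference = load_packaged_descriptor_matrix()
    computed = build_descriptor_matrix(
        load_packaged_solvents(), supplied={"DipoleZ": reference["DipoleZ"].to_dict()}
    )
    disc = verify_against_reference(
        computed,
        reference,
        tolerances={"SRW09": 0.5, "piPC05": 0.5, "Ram": 0.5, "X0Av": 0.002, "ATS6m": 0.01},
        known=KNOWN_DISCREPANT_CELLS,
    )
    return ReproductionReport(
        model_rows=model_rows,
        spot_checks=spot_checks,
        correlation_train=corr_train,
        correlation_all=corr_all,
        descriptor_discrepancies=disc,
        best_subsets=best_subsets,
        tolerances=tol,
    )


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "preset": "packaged",  # or "paperlike"
    "seed": 0,
    "max_vars": 4,
    "min_vars": 1,
    "fitness": "q2",
    "noise_sd": 0.25,
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        cfg = dict(_DEFAULT_CONFIG)
        for line in Path(config).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in ("seed", "max_vars", "min_vars"):
                cfg[key] = int(value)
            elif key == "noise_sd":
                cfg[key] = float(value)
            else:
                cfg[key] = value
        return cfg
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(config or {})
    return cfg


def run_pipeline(config, out_dir: str | Path) -> Path:
    """Run select → fit → validate end to end and write artifacts.

    ``config`` is a mapping or a path to a ``key = value`` file with keys
    ``preset`` (``packaged`` or ``paperlike``), ``seed``, ``min_vars``,
    ``max_vars``, ``fitness`` and (paperlike only) ``noise_sd``.  Artifacts:
    ``matrix.csv``, ``candidates.json``, ``model.json``, ``validation.json``
    plus ``manifest.json`` and ``run.log``.  Deterministic for a fixed seed.
    """
    cfg = _load_config(config)
    if cfg["preset"] not in ("packaged", "paperlike"):
        raise ValueError(f"unknown preset {cfg['preset']!r}")
    if cfg["max_vars"] < 1 or cfg["min_vars"] < 1 or cfg["min_vars"] > cfg["max_vars"]:
        raise ValueError(
            f"invalid variable bounds min={cfg['min_vars']} max={cfg['max_vars']}"
        )
    if cfg["fitness"] not in ("q2", "r2"):
        raise ValueError(f"invalid fitness {cfg['fitness']!r}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"nanodisp {__version__}", f"config: {json.dumps(cfg, sort_keys=True)}"]

    if cfg["preset"] == "packaged":
        records = load_packaged_solvents(with_smiles=False)
        matrix = load_packaged_descriptor_matrix()
    else:
        data = generate_paperlike_dataset(seed=cfg["seed"], noise_sd=cfg["noise_sd"])
        records, matrix = data.records, data.matrix
        log_lines.append(f"generating model: {data.truth}")

    y = pd.Series({r.id: r.log_conc for r in records})
    split = pd.Series({r.id: r.split for r in records})
    train_ids = split[split == "train"].index
    test_ids = split[split == "test"].index

    matrix.to_csv(out / "matrix.csv")

    ga_cfg = GAConfig(
        max_vars=cfg["max_vars"], min_vars=cfg["min_vars"],
        fitness=cfg["fitness"], seed=cfg["seed"],
    )
    candidates = ga_select(matrix.data.loc[train_ids], y.loc[train_ids], ga_cfg)
    cand_payload = {
        str(size): {"subset": list(c.subset), "fitness": round(c.fitness, 10)}
        for size, c in candidates.items()
    }
    (out / "candidates.json").write_text(
        json.dumps(cand_payload, indent=2, sort_keys=True), encoding="utf-8"
    )

    best = max(candidates.values(), key=lambda c: (c.fitness, -len(c.subset)))
    res = best.model
    model_payload = {
        "descriptors": list(best.subset),
        "coefficients": {k: round(float(v), 10) for k, v in res.params.items()},
        "halfwidths_ci95": {k: round(float(v), 10) for k, v in res.halfwidths.items()},
        "standard_errors": {k: round(float(v), 10) for k, v in res.bse.items()},
        "n": int(res.nobs),
        "R2": round(res.rsquared, 10),
        "s": round(res.s, 10),
        "F": round(res.fvalue, 10),
        "p": float(f"{res.f_pvalue:.6e}"),
        "PRESS": round(res.loo.press, 10),
        "Q2": round(res.loo.q2, 10),
        "SPRESS": round(res.loo.spress, 10),
        "SDEP": round(res.loo.sdep, 10),
    }
    (out / "model.json").write_text(
        json.dumps(model_payload, indent=2, sort_keys=True), encoding="utf-8"
    )

    rep = validate_model(res, matrix.data.loc[test_ids], y.loc[test_ids])
    val_payload = {
        "R2_test": round(rep.r2_test, 10),
        "rm2": round(rep.rm2, 10),
        "rm2_reverse": round(rep.rm2_reverse, 10),
        "rm2_average": round(rep.rm2_average, 10),
        "rm2_delta": round(rep.rm2_delta, 10),
        "pass_average": rep.pass_average,
        "pass_delta": rep.pass_delta,
    }
    (out / "validation.json").write_text(
        json.dumps(val_payload, indent=2, sort_keys=True), encoding="utf-8"
    )

    artifacts = ["matrix.csv", "candidates.json", "model.json", "validation.json"]
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "preset": cfg["preset"],
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    log_lines.append(f"artifacts: {', '.join(artifacts)}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
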