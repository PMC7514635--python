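"""Run orchestration: configuration, artifacts, manifests, diagnostics.

A run is described by a :class:`RunConfig` (JSON document with ``model``,
``sampler`` *or* ``enumeration``, ``zeros`` and ``analysis`` blocks plus a
master seed), executed by :func:`run_pipeline`:

    coefficient tables  ->  partition polynomials per N  ->  certified
    roots  ->  leading-zero trajectories per replicate  ->  finite-size-
    scaling estimates.

Artifacts are plain text (count-table TSV, zero-table TSV, analysis JSON)
tagged with a run id; the run manifest records the resolved configuration,
package version, per-replicate seeds, convention flags and SHA-256 digests
of every artifact, which :func:`audit_run` re-verifies.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from importlib.metadata import version as _dist_version

try:
    _pkg_version = _dist_version("trailzeros")
except Exception:  # pragma: no cover - not installed
    _pkg_version = "unknown"

from .enumeration import CountTable, enumerate_trails
from .flatperm import FlatPermConfig, run_flatperm
from .fss import (
    ZeroTrajectory,
    alpha_from_phi,
    asymptotic_window,
    extrapolate_critical,
    extrapolate_phi_eff,
    fit_phi_loglog,
    replicate_errors,
)
from .walks import ModelWeights
from .zeros import RootSet, build_polynomial, select_leading, solve_roots

logger = logging.getLogger("trailzeros")

_ZERO_COLUMNS = ("N", "variable", "Re", "Im", "residual", "rule", "replicate")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass
class RunConfig:
    """Typed, serializable description of one end-to-end run.

    ``sampler`` (FlatPERM) and ``enumeration`` (exact) are mutually
    exclusive; ``zeros.variable`` = ``"omega"`` requires a surface-mode
    model.  Round-trips through JSON exactly.
    """

    model: ModelWeights
    seed: int = 0
    sampler: Optional[FlatPermConfig] = None
    enumeration_n_max: Optional[int] = None
    zeros: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.sampler is None) == (self.enumeration_n_max is None):
            raise ValueError("exactly one of sampler / enumeration must be set")
        self.zeros = {**self._default_zeros(), **self.zeros}
        self.analysis = {**self._default_analysis(), **self.analysis}
        if self.zeros["variable"] == "omega" and not self.model.surface:
            raise ValueError("variable 'omega' requires a surface-mode model")

    def _default_zeros(self) -> dict:
        return {
            "variable": "omega" if self.model.surface else "tau",
            "window": [0.0, 20.0],
            "rule": "min_im",
            "n_min": 8,
            "n_stride": 2,
            "residual_tol": 1e-10,
        }

    def _default_analysis(self) -> dict:
        return {
            "degree": 3 if self.model.surface else 4,
            "phi_gaps": [2, 4],
            "parity": None,
        }

    @property
    def n_max(self) -> int:
        return self.sampler.n_max if self.sampler else self.enumeration_n_max

    def zero_grid(self) -> list[int]:
        return list(
            range(int(self.zeros["n_min"]), self.n_max + 1, int(self.zeros["n_stride"]))
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "seed": self.seed,
            "sampler": self.sampler.to_dict() if self.sampler else None,
            "enumeration": {"n_max": self.enumeration_n_max}
            if self.enumeration_n_max
            else None,
            "zeros": self.zeros,
            "analysis": self.analysis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sampler = d.get("sampler")
        enum = d.get("enumeration")
        return cls(
            model=ModelWeights.from_dict(d["model"]),
            seed=int(d.get("seed", 0)),
            sampler=FlatPermConfig.from_dict(sampler) if sampler else None,
            enumeration_n_max=enum["n_max"] if enum else None,
            zeros=d.get("zeros", {}),
            analysis=d.get("analysis", {}),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def run_id(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# zero tables


def write_zero_table(path, rows: Sequence[dict], run_id: str) -> None:
    with open(path, "w") as fh:
        fh.write("# trailzeros zero-table v1\n")
        fh.write(f"# run: {run_id}\n")
        fh.write("\t".join(_ZERO_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    [
                        str(row["N"]),
                        row["variable"],
                        repr(float(row["Re"])),
                        repr(float(row["Im"])),
                        repr(float(row["residual"])),
                        row["rule"],
                        str(row["replicate"]),
                    ]
                )
                + "\n"
            )


def write_zero_json(path, rows: Sequence[dict], run_id: str) -> None:
    """JSON alternative to the zero-table TSV, values as decimal strings.

    ``repr`` of a float round-trips exactly, so the JSON and TSV dialects
    carry identical information.
    """
    payload = {
        "format": "trailzeros zero-table v1",
        "run": run_id,
        "zeros": [
            {
                "N": int(row["N"]),
                "variable": row["variable"],
                "Re": repr(float(row["Re"])),
                "Im": repr(float(row["Im"])),
                "residual": repr(float(row["residual"])),
                "rule": row["rule"],
                "replicate": int(row["replicate"]),
            }
            for row in rows
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_zero_json(path) -> pd.DataFrame:
    payload = json.loads(Path(path).read_text())
    df = pd.DataFrame(payload["zeros"])
    for col in ("Re", "Im", "residual"):
        df[col] = df[col].astype(float)
    return df


def read_zero_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_ZERO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing zero-table columns {sorted(missing)}")
    return df


def trajectory_from_zero_table(df: pd.DataFrame) -> ZeroTrajectory:
    lead = df[df["rule"] != "-"]
    frame = pd.DataFrame(
        {
            "N": lead["N"].astype(int),
            "re": lead["Re"].astype(float),
            "im": lead["Im"].astype(float),
            "replicate": lead["replicate"].astype(int),
        }
    )
    variable = str(df["variable"].iloc[0])
    return ZeroTrajectory(frame, variable=variable)


# ---------------------------------------------------------------------------
# pipeline


def _stage(name):
    def wrap(fn):
        def inner(*args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("tables")
def _make_tables(config: RunConfig) -> list[CountTable]:
    if config.enumeration_n_max is not None:
        return [enumerate_trails(config.model, config.enumeration_n_max)]
    estimates = run_flatperm(config.model, config.sampler)
    for est in estimates:
        logger.info(
            "replicate %d: %d tours, %d growth steps",
            est.replicate, est.tours, est.steps,
        )
    return [est.table for est in estimates]


@_stage("zeros")
def _make_zeros(config: RunConfig, tables: Sequence[CountTable]):
    variable = config.zeros["variable"]
    window = tuple(config.zeros["window"])
    rule = config.zeros["rule"]
    tol = float(config.zeros["residual_tol"])
    all_rows = []
    rootsets: list[dict[int, RootSet]] = []
    trajectories = []
    for rep, table in enumerate(tables):
        rows = []
        per_n: dict[int, RootSet] = {}
        leads = []
        prev = None
        for n in config.zero_grid():
            if n > table.n_max or not table.slice(n):
                continue
            poly = build_polynomial(table, n, variable)
            roots = solve_roots(poly, residual_tol=tol)
            per_n[n] = roots
            lead = select_leading(roots, rule=rule, window=window, prev=prev)
            if lead is not None:
                prev = lead
                leads.append(lead)
            lead_val = lead.value if lead is not None else None
            for z, res in zip(roots.roots, roots.residuals):
                is_lead = lead_val is not None and z == lead_val
                rows.append(
                    {
                        "N": n,
                        "variable": variable,
                        "Re": z.real,
                        "Im": z.imag,
                        "residual": res,
                        "rule": rule if is_lead else "-",
                        "replicate": rep,
                    }
                )
        if leads:
            trajectories.append(
                ZeroTrajectory.from_leading_zeros(leads, replicate=rep)
            )
        rootsets.append(per_n)
        all_rows.append(rows)
    traj = ZeroTrajectory.concat(trajectories) if trajectories else None
    return all_rows, rootsets, traj


@_stage("analysis")
def analyze_trajectory(traj: ZeroTrajectory, analysis: dict) -> dict:
    """Finite-size-scaling estimates from a leading-zero trajectory.

    Reports the critical-point extrapolation (Re vs Im polynomial), both
    cross-over-exponent estimators, the specific-heat exponent, parity-
    resolved variants, and replicate/window spreads.
    """
    degree = int(analysis.get("degree", 4))
    parity = analysis.get("parity")
    report: dict = {"variable": traj.variable}
    crit = extrapolate_critical(traj, degree=degree, parity=parity)
    report["critical"] = {
        "value": crit.value,
        "stderr": crit.stderr,
        "degree": crit.degree,
        "data_range": list(crit.data_range),
    }
    window = asymptotic_window(traj, parity=parity)
    phi_ll = fit_phi_loglog(traj, window=window, parity=parity)
    report["phi_loglog"] = {
        "value": phi_ll.value,
        "stderr": phi_ll.stderr,
        "window": list(phi_ll.window),
        "drift": phi_ll.drift,
    }
    try:
        phi_ratio = extrapolate_phi_eff(traj, gaps=analysis.get("phi_gaps", [2, 4]))
        report["phi_ratio"] = {
            "value": phi_ratio.value,
            "stderr": phi_ratio.stderr,
            "window": list(phi_ratio.window),
        }
    except (ValueError, KeyError):
        report["phi_ratio"] = None
    alpha, alpha_se = alpha_from_phi(phi_ll)
    report["alpha"] = {"value": alpha, "stderr": alpha_se}
    # parity-resolved critical estimates
    report["critical_by_parity"] = {}
    for par in (0, 1):
        try:
            c = extrapolate_critical(traj, degree=degree, parity=par)
            report["critical_by_parity"][str(par)] = {
                "value": c.value, "stderr": c.stderr,
            }
        except ValueError:
            report["critical_by_parity"][str(par)] = None
    # replicate and extremal-fit spreads for the critical point
    rep_estimates = []
    for rep in traj.replicates():
        sub = ZeroTrajectory(
            traj.frame[traj.frame["replicate"] == rep], traj.variable
        )
        try:
            rep_estimates.append(extrapolate_critical(sub, degree=degree).value)
        except ValueError:
            pass
    window_estimates = []
    for deg in sorted({max(1, degree - 1), degree, min(6, degree + 1)}):
        try:
            window_estimates.append(extrapolate_critical(traj, degree=deg).value)
        except ValueError:
            pass
    if rep_estimates:
        report["critical_spreads"] = replicate_errors(rep_estimates, window_estimates)
    return report


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute tables -> zeros -> finite-size scaling and write artifacts.

    Writes per-replicate count-table and zero-table TSVs, an analysis JSON
    and a manifest JSON into ``outdir``; returns the analysis report.  A
    second run with the same config and seed writes byte-identical tables
    and manifest.  Stage failures raise :class:`PipelineError` tagged with
    the stage name; artifacts written before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_id = config.run_id()
    tables = _make_tables(config)
    table_paths = []
    for rep, table in enumerate(tables):
        path = outdir / f"table_rep{rep}.tsv"
        table.meta["run"] = run_id
        table.to_tsv(path)
        table_paths.append(path)
    zero_rows, rootsets, traj = _make_zeros(config, tables)
    zero_paths = []
    for rep, rows in enumerate(zero_rows):
        path = outdir / f"zeros_rep{rep}.tsv"
        write_zero_table(path, rows, run_id)
        zero_paths.append(path)
    if traj is None:
        # low-degree polynomials may have no zeros in the physical window;
        # the tables and root sets are still valid artifacts
        report = {"variable": config.zeros["variable"], "critical": None,
                  "note": "no leading zeros on the requested grid"}
    else:
        try:
            report = analyze_trajectory(traj, config.analysis)
        except (PipelineError, ValueError) as exc:
            report = {"variable": config.zeros["variable"], "critical": None,
                      "note": f"analysis degraded: {exc}"}
    if len(rootsets) >= 2:
        try:
            report["convergence"] = validate_convergence(rootsets)
        except ValueError as exc:
            report["convergence"] = {"error": str(exc)}
    report["run"] = run_id
    analysis_path = outdir / "analysis.json"
    analysis_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    # plot-ready trajectory TSV
    traj_path = outdir / "trajectory.tsv"
    with open(traj_path, "w") as fh:
        fh.write("# trailzeros trajectory v1\n")
        fh.write(f"# run: {run_id}\n")
        if traj is not None:
            traj.frame.to_csv(fh, sep="\t", index=False)
        else:
            fh.write("N\tre\tim\treplicate\n")
    manifest = {
        "run": run_id,
        "version": _pkg_version,
        "config": config.to_dict(),
        "seeds": config.sampler.replicate_seeds() if config.sampler else [],
        "conventions": {
            "surface_convention": config.model.surface_convention,
            "endpoint_degenerate": "collision",
        },
        "artifacts": {
            p.name: _sha256(p)
            for p in table_paths + zero_paths + [analysis_path, traj_path]
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return report


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# diagnostics


def validate_convergence(
    rootsets: Sequence[dict[int, RootSet]],
    window: tuple[float, float] = (0.0, 20.0),
    k_zeros: int = 3,
    threshold: float = 0.05,
) -> dict:
    """Replicate-superposition diagnostic for stochastic zero estimates.

    For each common N, the k-th zero (ordered by closeness to the positive
    real axis, i.e. by imaginary part within the positive-Re window) is
    compared across replicates; the dispersion is the maximum pairwise
    distance.  The run passes when the leading-zero dispersion is below
    ``threshold`` and smaller than the dispersion of the ``k_zeros``-th
    zero — leading zeros must superpose while deeper zeros may scatter.
    """
    if len(rootsets) < 2:
        raise ValueError("convergence validation needs >= 2 replicates")
    grids = [set(rs.keys()) for rs in rootsets]
    common = set.intersection(*grids)
    if grids[0] != common or not common:
        raise ValueError("replicate zero tables are on mismatched N grids")
    disp = np.zeros(k_zeros)
    counts = np.zeros(k_zeros, dtype=int)
    for n in sorted(common):
        ordered = []
        for rs in rootsets:
            roots = rs[n].roots
            cand = roots[
                (roots.imag > 0) & (roots.real > window[0]) & (roots.real < window[1])
            ]
            ordered.append(cand[np.argsort(cand.imag)])
        for k in range(k_zeros):
            if all(len(o) > k for o in ordered):
                zs = np.array([o[k] for o in ordered])
                d = np.abs(zs[:, None] - zs[None, :]).max()
                disp[k] += d
                counts[k] += 1
    if counts[0] == 0:
        raise ValueError("no common leading zeros to compare")
    mean_disp = [float(disp[k] / counts[k]) if counts[k] else None
                 for k in range(k_zeros)]
    deepest = mean_disp[k_zeros - 1]
    passed = mean_disp[0] < threshold and (
        deepest is None or mean_disp[0] <= deepest
    )
    return {
        "dispersion_by_zero": mean_disp,
        "threshold": threshold,
        "pass": bool(passed),
    }


def audit_run(outdir) -> dict:
    """Verify that every artifact matches the manifest that produced it.

    Checks that each file listed in the manifest exists with the recorded
    SHA-256 digest and that no dangling artifact files (tagged TSV/JSON
    outputs absent from the manifest) remain in the directory.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        return {"pass": False, "errors": ["manifest.json missing"]}
    manifest = json.loads(manifest_path.read_text())
    errors = []
    for name, digest in manifest.get("artifacts", {}).items():
        path = outdir / name
        if not path.exists():
            errors.append(f"missing artifact {name}")
        elif _sha256(path) != digest:
            errors.append(f"digest mismatch for {name}")
    listed = set(manifest.get("artifacts", {}))
    for path in outdir.iterdir():
        if path.name in ("manifest.json",) or path.is_dir():
            continue
        if path.suffix in (".tsv", ".json") and path.name not in listed:
            errors.append(f"dangling artifact {path.name}")
    return {"pass": not errors, "errors": errors, "run": manifest.get("run")}
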