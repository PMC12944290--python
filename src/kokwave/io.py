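"""File formats, configuration and the end-to-end pipeline.

Flash sequences travel as two-column CSV (flash, yield) with a header;
decompositions as four-column CSV (flash, raw, period4, period2); fit
results as JSON reports and flat CSV rows.  All floats are serialized
with ``repr``-level precision (17 significant digits) so write→read is
the identity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acceptor import compare_dynamics, normalize_pair, predict_qb_minus
from .errors import FormatError, KokwaveError, ValidationError
from .ewt import filter_signal
from .fit import FitResult, fit_vzad
from .kok import simulate_yields
from .synth import InterferenceSpec, combine_signals, generate_interference
from .types import FlashYieldSequence, KokParameters, SStateDistribution

__all__ = [
    "PipelineConfig",
    "read_flash_csv",
    "write_flash_csv",
    "write_decomposition_csv",
    "write_fit_report",
    "fit_result_row",
    "read_config",
    "run_pipeline",
]

_FLOAT_FMT = "%.17g"


def read_flash_csv(path: str | Path, filtered: bool = False) -> FlashYieldSequence:
    """Read a two-column (flash, yield) CSV with a header line.

    Flash indices must be consecutive integers starting at 1; gaps,
    duplicates or non-numeric yields are format errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (flash, yield)")
    flash_col, yield_col = df.columns[0], df.columns[1]
    flashes = pd.to_numeric(df[flash_col], errors="coerce")
    yields = pd.to_numeric(df[yield_col], errors="coerce")
    if flashes.isna().any():
        raise FormatError(f"{path}: non-numeric flash index")
    if yields.isna().any():
        raise FormatError(f"{path}: non-numeric yield value")
    idx = flashes.to_numpy()
    expected = np.arange(1, len(idx) + 1)
    if not np.array_equal(idx, expected):
        raise FormatError(
            f"{path}: flash indices must be consecutive from 1; got {idx.tolist()}"
        )
    return FlashYieldSequence(yields=yields.to_numpy(float), filtered=filtered)


def write_flash_csv(seq: FlashYieldSequence, path: str | Path) -> None:
    df = pd.DataFrame({"flash": seq.flashes, "yield": seq.yields})
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def write_decomposition_csv(
    raw: FlashYieldSequence,
    period_four: FlashYieldSequence,
    period_two: FlashYieldSequence,
    path: str | Path,
) -> None:
    df = pd.DataFrame({
        "flash": raw.flashes,
        "raw": raw.yields,
        "period4": period_four.yields,
        "period2": period_two.yields,
    })
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def write_fit_report(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.as_dict(), indent=2) + "\n")


def fit_result_row(fit: FitResult, label: str = "") -> pd.DataFrame:
    """One flat CSV row per fit for batch comparison tables."""
    row = {"label": label, **fit.params.as_dict(), **fit.init.as_dict(),
           "scale": fit.scale, "sse": fit.sse}
    return pd.DataFrame([row])


@dataclass
class PipelineConfig:
    """One run of the full decompose→fit→compare pipeline.

    Exactly one of ``input_path`` (experimental CSV) or ``simulation``
    (parameter block) must be set.
    """

    output_dir: str | Path
    input_path: str | Path | None = None
    simulation: dict | None = None
    ewt: dict = field(default_factory=dict)       # taper, maxima_threshold
    fit: dict = field(default_factory=dict)       # constrain_dark_adapted, seed
    n_flashes: int = 20
    seed: int = 1

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValidationError(
                "config must set exactly one of input_path or simulation"
            )


def read_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {"output_dir", "input_path", "simulation", "ewt", "fit",
             "n_flashes", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def _simulation_inputs(block: dict) -> tuple[KokParameters, SStateDistribution, InterferenceSpec | None]:
    params = KokParameters(
        alpha=block.get("alpha", 0.0), beta=block.get("beta", 0.0),
        gamma=block.get("gamma", 1.0), delta=block.get("delta", 0.0),
        epsilon=block.get("epsilon", 0.0),
    )
    init = SStateDistribution(
        s0=block.get("s0", 0.0), s1=block.get("s1", 0.0),
        s2=block.get("s2", 0.0), s3=block.get("s3", 0.0),
        s_eps=block.get("s_eps", 0.0),
    )
    spec = None
    if "interference" in block:
        b = block["interference"]
        spec = InterferenceSpec(
            amplitude=b["amplitude"], damping=b.get("damping", 0.8),
            phase=b.get("phase", +1),
        )
    return params, init, spec


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run decompose → raw fit + EWT fit → semiquinone comparison.

    Writes, under ``config.output_dir``: the input sequence, the
    decomposition CSV, both fit reports (JSON) and the combined fit
    table (CSV), the Q_B⁻ comparison CSV, and a run log with the config
    hash and seeds.  On any stage failure, partial outputs are removed
    and the error is re-raised tagged with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "input"
        if config.simulation is not None:
            params, init, spec = _simulation_inputs(config.simulation)
            kok = simulate_yields(params, init, config.n_flashes)
            seq = kok
            if spec is not None:
                seq = combine_signals(kok, generate_interference(spec, config.n_flashes))
        else:
            seq = read_flash_csv(config.input_path)
        input_csv = out / "input_sequence.csv"
        write_flash_csv(seq, input_csv)
        written["input"] = input_csv

        stage = "decompose"
        taper = config.ewt.get("taper", 0.5)
        threshold = config.ewt.get("maxima_threshold", 0.01)
        p4, p2 = filter_signal(seq, retention_threshold=threshold, taper=taper)
        dec_csv = out / "decomposition.csv"
        write_decomposition_csv(seq, p4, p2, dec_csv)
        written["decomposition"] = dec_csv

        stage = "fit"
        fit_kwargs = dict(
            constrain_dark_adapted=config.fit.get("constrain_dark_adapted", True),
            seed=config.fit.get("seed", config.seed),
        )
        raw_fit = fit_vzad(seq, **fit_kwargs)
        ewt_fit = fit_vzad(p4, **fit_kwargs)
        raw_json = out / "raw_fit.json"
        ewt_json = out / "ewt_fit.json"
        write_fit_report(raw_fit, raw_json)
        write_fit_report(ewt_fit, ewt_json)
        written["raw_fit"] = raw_json
        written["ewt_fit"] = ewt_json
        table = pd.concat([
            fit_result_row(raw_fit, "raw_fit"),
            fit_result_row(ewt_fit, "ewt_fit"),
        ], ignore_index=True)
        table_csv = out / "fit_table.csv"
        table.to_csv(table_csv, index=False, float_format=_FLOAT_FMT)
        written["fit_table"] = table_csv

        stage = "qb_compare"
        pred = predict_qb_minus(ewt_fit.params.gamma, len(seq))
        p2_c, pred_c = normalize_pair(p2, pred)
        report = compare_dynamics(p2_c, pred_c)
        qb_csv = out / "qb_comparison.csv"
        pd.DataFrame(report.paired_values,
                     columns=["flash", "period2", "predicted_scaled"]).to_csv(
            qb_csv, index=False, float_format=_FLOAT_FMT)
        written["qb_comparison"] = qb_csv
        qb_summary = out / "qb_summary.json"
        qb_summary.write_text(json.dumps({
            "pearson_r": report.pearson_r,
            "phase_agreement": report.phase_agreement,
            "damping_ratio_experimental": report.damping_ratio_experimental,
            "damping_ratio_predicted": report.damping_ratio_predicted,
            "gamma": ewt_fit.params.gamma,
        }, indent=2) + "\n")
        written["qb_summary"] = qb_summary

        stage = "log"
        config_dict = {
            "output_dir": str(config.output_dir),
            "input_path": None if config.input_path is None else str(config.input_path),
            "simulation": config.simulation,
            "ewt": config.ewt, "fit": config.fit,
            "n_flashes": config.n_flashes, "seed": config.seed,
        }
        blob = json.dumps(config_dict, sort_keys=True)
        log = out / "run_log.json"
        log.write_text(json.dumps({
            "config": config_dict,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": config.seed,
            "outputs": {k: str(v) for k, v in written.items()},
        }, indent=2) + "\n")
        written["run_log"] = log
        return written
    except KokwaveError as exc:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
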