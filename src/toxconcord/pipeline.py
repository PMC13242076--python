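"""End-to-end orchestration: scoring -> matching -> harmonization ->
statistics -> report tables.

The report bundle mirrors the published analysis surfaces in tidy,
machine-readable form (one row per stratum x domain):

* ``agreement``   — 4-level analysis: matched n, quadratic-weighted
  kappa, p-value, interpretation (Table-2-style);
* ``binary``      — none-vs-any 2x2 cells with percentages and
  unweighted kappa (Table-3-style);
* ``underreport`` — underreport/overestimate rate matrix
  (Figure-1-style);
* ``change``      — mid-to-end change in discordance on the paired
  subset, with McNemar p (Figure-2-style);
* ``predominance``— exact binomial test of underreporting predominance
  among discordant pairs.

Outputs are deterministic for fixed inputs; a manifest records the
config hash and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    DegenerateTableError,
    WeightScheme,
    binary_concordance_summary,
    build_contingency_table,
    cohen_kappa,
    round_half_up,
)
from .discordance import (
    DEFAULT_ALPHA,
    discordance_change,
    discordance_summary,
    exact_binomial_predominance,
)
from .domains import DOMAINS, Arm, Timepoint, ValidationError
from .io import read_ctcae_table, read_eortc_responses
from .matching import match_observations
from .scoring import score_severities

logger = logging.getLogger("toxconcord")


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run."""

    ctcae_path: Union[str, Path]
    eortc_path: Union[str, Path]
    out_dir: Union[str, Path]
    alpha: float = DEFAULT_ALPHA
    formats: tuple[str, ...] = ("csv", "json")
    domains: tuple[str, ...] = tuple(DOMAINS)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        unknown = [d for d in self.domains if d not in DOMAINS]
        if unknown:
            raise ValidationError(f"unknown domain(s) in config: {unknown}")
        bad = [f for f in self.formats if f not in ("csv", "json")]
        if bad:
            raise ValidationError(f"unsupported report format(s): {bad}")

    @classmethod
    def from_mapping(cls, data: dict, **overrides) -> "AnalysisConfig":
        known = {
            k: v
            for k, v in data.items()
            if k in ("ctcae_path", "eortc_path", "out_dir", "alpha", "formats", "domains")
        }
        known.update(overrides)
        if "formats" in known:
            known["formats"] = tuple(known["formats"])
        if "domains" in known:
            known["domains"] = tuple(known["domains"])
        return cls(**known)


@dataclass
class ReportBundle:
    agreement: pd.DataFrame
    binary: pd.DataFrame
    underreport: pd.DataFrame
    change: pd.DataFrame
    predominance: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "agreement": self.agreement,
            "binary": self.binary,
            "underreport": self.underreport,
            "change": self.change,
            "predominance": self.predominance,
        }


def _fmt_p(p: Optional[float]) -> Optional[str]:
    if p is None:
        return None
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full concordance analysis and write the report bundle."""
    ctcae = read_ctcae_table(config.ctcae_path)
    responses = read_eortc_responses(config.eortc_path)
    domains = [DOMAINS[name] for name in config.domains]
    severities = score_severities(responses, domains)
    logger.info(
        "loaded %d clinician records, %d item responses, %d scored severities",
        len(ctcae), len(responses), len(severities),
    )

    agreement_rows, binary_rows, under_rows, pred_rows, change_rows = [], [], [], [], []
    matched_cache: dict[tuple, list] = {}

    for arm in (Arm.A, Arm.B):
        arm_records = [r for r in ctcae if r.arm == arm]
        for tp in (Timepoint.MID, Timepoint.END):
            for domain in domains:
                stratum = {"arm": arm.value, "timepoint": tp.value, "domain": domain.name}
                pairs = match_observations(arm_records, severities, domain, tp)
                matched_cache[(arm, tp, domain.name)] = pairs
                logger.info(
                    "stratum arm=%s timepoint=%s domain=%s matched n=%d",
                    arm.value, tp.value, domain.name, len(pairs),
                )
                if not pairs:
                    agreement_rows.append({**stratum, "n": 0})
                    continue
                # 4-level agreement (Table-2-style)
                table4 = build_contingency_table(pairs, mode="ordinal4")
                try:
                    kr = cohen_kappa(table4, WeightScheme.QUADRATIC)
                    agreement_rows.append(
                        {
                            **stratum,
                            "n": kr.n,
                            "kappa": round_half_up(kr.kappa, 2),
                            "p_value": kr.p_value,
                            "p_display": _fmt_p(kr.p_value),
                            "label": kr.label,
                        }
                    )
                except DegenerateTableError:
                    agreement_rows.append(
                        {**stratum, "n": table4.n, "kappa": None, "label": "undefined"}
                    )
                # binary analysis (Table-3-style)
                binary_rows.append({**stratum, **binary_concordance_summary(pairs)})
                # discordance rates + predominance test
                summ = discordance_summary(pairs)
                under_rows.append(
                    {
                        **stratum,
                        "n": summ.n,
                        "underreport_pct": round_half_up(100 * summ.rate_under, 1),
                        "overestimate_pct": round_half_up(100 * summ.rate_over, 1),
                        "agreement_pct": round_half_up(100 * summ.rate_agree, 1),
                    }
                )
                if summ.n_under + summ.n_over > 0:
                    test = exact_binomial_predominance(
                        summ.n_under, summ.n_over, alpha=config.alpha
                    )
                    pred_rows.append(
                        {
                            **stratum,
                            "n_under": summ.n_under,
                            "n_over": summ.n_over,
                            "p_value": test.p_value,
                            "p_display": _fmt_p(test.p_value),
                            "significant": bool(test.significant),
                            "alpha": config.alpha,
                        }
                    )
            # mid-to-end change per domain within this arm
        for domain in domains:
            mid = matched_cache.get((arm, Timepoint.MID, domain.name), [])
            end = matched_cache.get((arm, Timepoint.END, domain.name), [])
            if not mid or not end:
                continue
            try:
                chg = discordance_change(mid, end)
            except ValidationError:
                continue
            change_rows.append(
                {
                    "arm": arm.value,
                    "domain": domain.name,
                    "n_paired": chg.n_paired,
                    "underreport_mid_pct": round_half_up(100 * chg.rate_mid, 1),
                    "underreport_end_pct": round_half_up(100 * chg.rate_end, 1),
                    "delta_pct_points": round_half_up(chg.delta_pct_points, 1),
                    "mcnemar_p": chg.test.p_value,
                    "mcnemar_method": chg.test.method,
                }
            )

    bundle = ReportBundle(
        agreement=pd.DataFrame(agreement_rows),
        binary=pd.DataFrame(binary_rows),
        underreport=pd.DataFrame(under_rows),
        change=pd.DataFrame(change_rows),
        predominance=pd.DataFrame(pred_rows),
        manifest=_manifest(config),
    )
    write_bundle(bundle, config.out_dir, config.formats)
    return bundle


def _manifest(config: AnalysisConfig) -> dict:
    cfg = {
        "ctcae_path": str(config.ctcae_path),
        "eortc_path": str(config.eortc_path),
        "alpha": config.alpha,
        "domains": list(config.domains),
        "formats": list(config.formats),
    }
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    return {
        "tool": "toxconcord",
        "version": __version__,
        "config": cfg,
        "config_sha256": digest,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


def write_bundle(
    bundle: ReportBundle, out_dir: Union[str, Path], formats: tuple[str, ...]
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        if "csv" in formats:
            df.to_csv(out / f"{name}.csv", index=False)
        if "json" in formats:
            (out / f"{name}.json").write_text(
                df.to_json(orient="records", indent=2, double_precision=12) + "\n"
            )
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2) + "\n")


def format_wide_agreement(agreement: pd.DataFrame) -> pd.DataFrame:
    """Render the tidy agreement table in the wide journal-style layout
    (domains as rows, arm x time point column blocks)."""
    wide = agreement.pivot(
        index="domain", columns=["timepoint", "arm"], values=["n", "kappa"]
    )
    return wide.sort_index(axis=1, level=[1, 2])
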