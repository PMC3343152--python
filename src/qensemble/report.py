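"""Per-peptide summary assembly and peptide-to-peptide comparison.

One summary run collects, for a single ensemble: mean Ramachandran
region populations and the alpha-tilde repeat percentage, per-residue
region profiles, DSSP-subset secondary-structure content (helix / turn
/ other), helix-segment statistics, turn typing, motif prevalence at
both strand-length variants, odds-ratio correlation profiles for the
four regions and the alpha-tilde property plus the Pearson-psi profile,
and (when coordinates are present) the radius-of-gyration analysis with
prolyl cis/trans sub-ensembles.  Every run echoes its configuration and
seed in a provenance block.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .correlation import (dominant_period, long_range_flag, or_profile,
                          pearson_psi_profile, region_mask)
from .ensemble_io import ConformationEnsemble
from .rama_regions import (REGION_NAMES, RegionBoundarySet, RegionLabelMatrix,
                           alpha_tilde_mask, assign_regions_cluster,
                           assign_regions_hard, mean_region_populations,
                           region_population_profile, MISSING_LABEL)
from .rg_analysis import (fit_gaussian_mixture, prolyl_isomers,
                          rg_histogram, rg_per_conformation)
from .ss_motifs import (HELIX_CODES, assign_ss, classify_turns,
                        detect_hairpins, detect_strands, helix_segment_stats,
                        motif_prevalence)


class ConfigError(ValueError):
    """Unknown or out-of-range configuration value."""


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with documented ranges."""

    assignment: str = "cluster"        # hard | cluster
    grid_deg: float = 5.0              # Ramachandran histogram bin width
    trim: int | None = None            # end residues omitted; None = auto
    r_max: int | None = None
    shift_deg: float = 100.0           # psi shift before Pearson correlation
    temperature_K: float = 300.0
    histogram_window: float = 0.5      # angstrom
    strand_min_lens: tuple = (3, 4)
    max_loop: int = 8
    pooling: str = "pooled"            # pooled | per_pair
    correction: bool = True            # Haldane-Anscombe on zero cells
    mixture_components: int = 1
    r_tail: int = 10
    seed: int = 0
    boundaries: RegionBoundarySet | None = None

    def __post_init__(self):
        if self.assignment not in ("hard", "cluster"):
            raise ConfigError(f"assignment must be hard|cluster, got {self.assignment!r}")
        if self.pooling not in ("pooled", "per_pair"):
            raise ConfigError(f"pooling must be pooled|per_pair, got {self.pooling!r}")
        if self.temperature_K <= 0:
            raise ConfigError("temperature_K must be positive")
        if self.histogram_window <= 0:
            raise ConfigError("histogram_window must be positive")
        if self.mixture_components < 1:
            raise ConfigError("mixture_components must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("boundaries")
        d["strand_min_lens"] = list(self.strand_min_lens)
        return d


def _profile_record(profile, r_tail):
    rec = {
        "r": profile.r.tolist(),
        "value": [None if not np.isfinite(v) else float(v) for v in profile.value],
        "n_pairs": profile.n_pairs.tolist(),
        "trim": profile.trim,
        "statistic_kind": profile.statistic_kind,
    }
    if profile.se is not None:
        rec["se"] = [float(s) for s in profile.se]
    try:
        flag, tail_mean, threshold = long_range_flag(profile, r_tail)
        rec["long_range"] = {"flag": bool(flag), "tail_mean": tail_mean,
                             "threshold": threshold}
    except ValueError:
        rec["long_range"] = None
    try:
        period, power = dominant_period(profile)
        rec["dominant_period"] = {"period": period, "power_fraction": power}
    except ValueError:
        rec["dominant_period"] = None
    return rec


def _ensemble_hash(ens: ConformationEnsemble) -> str:
    h = hashlib.sha256()
    for arr in (ens.phi, ens.psi, ens.omega):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def run_summary(ens: ConformationEnsemble, cfg: AnalysisConfig | None = None,
                labels: RegionLabelMatrix | None = None) -> dict:
    """Full per-peptide analysis report as a JSON-serializable dict."""
    cfg = cfg or AnalysisConfig()
    bounds = cfg.boundaries or RegionBoundarySet()
    if labels is None:
        if cfg.assignment == "cluster":
            labels = assign_regions_cluster(ens, bounds, cfg.grid_deg)
        else:
            labels = assign_regions_hard(ens, bounds)

    report = {
        "peptide": ens.peptide_name,
        "n_conformations": ens.n_conformations,
        "n_residues": ens.n_residues,
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "input_hash": _ensemble_hash(ens),
        },
    }

    # --- Ramachandran regions
    report["region_populations"] = mean_region_populations(labels)
    prof = region_population_profile(labels)
    report["region_profile"] = {
        "residue": prof["residue"].tolist(),
        **{name: np.round(prof[name], 4).tolist() for name in REGION_NAMES},
    }

    # --- secondary structure (requires coordinates)
    gln = ens.gln_mask()
    at_mask = alpha_tilde_mask(labels).astype(np.int8)
    at_mask[labels.labels == MISSING_LABEL] = -1
    ss_strings = hbond_lists = None
    if ens.coords is not None:
        ss_strings, hbond_lists = assign_ss(ens)
        helix = turn = 0
        total = ens.n_conformations * int(gln.sum())
        for s in ss_strings:
            arr = np.array(list(s))
            helix += int((np.isin(arr, list(HELIX_CODES)) & gln).sum())
            turn += int((np.isin(arr, ["T", "S"]) & gln).sum())
        report["ss_content"] = {
            "helix": 100.0 * helix / total,
            "turn": 100.0 * turn / total,
            "other": 100.0 * (total - helix - turn) / total,
        }
        report["helix_stats"] = helix_segment_stats(ss_strings, ens.residue_names)
        turn_table = classify_turns(ss_strings, hbond_lists, labels)
        turn_table.pop("turns")
        report["turn_table"] = turn_table

        instances = []
        for min_len in cfg.strand_min_lens:
            for kind in ("beta", "alpha_tilde", "ppii"):
                instances.extend(detect_strands(labels, hbond_lists, kind, min_len))
            for kind in ("beta", "alpha_tilde"):
                instances.extend(
                    detect_hairpins(labels, ss_strings, hbond_lists, kind,
                                    min_len, cfg.max_loop)
                )
        prevalence = motif_prevalence(instances, ens)
        report["motif_prevalence"] = {
            f"{t}_min{v}": p for (t, v), p in prevalence.items()
        }

    # --- correlation profiles
    profiles = {}
    for region in REGION_NAMES:
        p = or_profile(region_mask(labels, region), r_max=cfg.r_max,
                       trim=cfg.trim, pooling=cfg.pooling,
                       temperature=cfg.temperature_K,
                       correction=cfg.correction, residue_columns=gln,
                       region=region)
        profiles[f"or_{region}"] = p
    profiles["or_alpha_tilde"] = or_profile(
        at_mask, r_max=cfg.r_max, trim=cfg.trim, pooling=cfg.pooling,
        temperature=cfg.temperature_K, correction=cfg.correction,
        residue_columns=gln, statistic_kind="or_alpha_tilde")
    profiles["pearson_psi"] = pearson_psi_profile(
        ens, shift_deg=cfg.shift_deg, r_max=cfg.r_max, trim=cfg.trim)
    report["correlation"] = {
        key: _profile_record(p, cfg.r_tail) for key, p in profiles.items()
    }
    report["_profiles"] = profiles  # in-memory products, stripped on write

    # --- radius of gyration
    if ens.coords is not None:
        rg = rg_per_conformation(ens)
        hist = rg_histogram(rg, cfg.histogram_window)
        rg_rec = {
            "mean": float(rg.mean()),
            "sd": float(rg.std(ddof=1)) if rg.size > 1 else 0.0,
            "n": int(rg.size),
            "window": cfg.histogram_window,
        }
        try:
            fit = fit_gaussian_mixture(hist, cfg.mixture_components)
            rg_rec["mixture"] = {
                "k": fit.k,
                "weights": fit.weights.tolist(),
                "means": fit.means.tolist(),
                "sds": fit.sds.tolist(),
                "reduced_chi2": fit.reduced_chi2,
            }
        except (ValueError, RuntimeError):
            rg_rec["mixture"] = None
        if any(n == "PRO" for n in ens.residue_names):
            state, ens_trans, ens_cis = prolyl_isomers(ens)
            rg_rec["prolyl"] = {
                "trans_percent": state.trans_percent.tolist(),
                "all_trans_percent": float(100.0 * state.all_trans.mean()),
                "rg_mean_all_trans": (
                    float(rg_per_conformation(ens_trans).mean())
                    if ens_trans.n_conformations else None),
                "rg_mean_cis_containing": (
                    float(rg_per_conformation(ens_cis).mean())
                    if ens_cis.n_conformations else None),
            }
        report["rg"] = rg_rec
    return report


def _flatten(d, prefix=""):
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (int, float)) and not isinstance(v, bool):
            out[key] = float(v)
    return out


def compare_peptides(reports: list[dict]) -> dict:
    """Side-by-side differences of scalar summary quantities.

    The first report is the reference; differences are other - reference.
    Long-range flags are reported per peptide; correlation-tail means
    get pooled standard errors.
    """
    import logging

    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    configs = [r["provenance"]["config"] for r in reports]
    if any(c != configs[0] for c in configs[1:]):
        logging.getLogger(__name__).warning(
            "comparing reports with mismatched configurations")
    names = [r["peptide"] for r in reports]
    skip = ("provenance", "_profiles", "region_profile", "correlation")
    flats = [
        _flatten({k: v for k, v in r.items() if k not in skip and isinstance(v, dict)})
        for r in reports
    ]
    shared = sorted(set(flats[0]).intersection(*flats[1:]))
    table = {
        key: {
            "values": [f[key] for f in flats],
            "delta_vs_first": [f[key] - flats[0][key] for f in flats],
        }
        for key in shared
    }
    tails = {}
    for key in reports[0].get("correlation", {}):
        rows = []
        for r in reports:
            rec = r["correlation"].get(key, {}).get("long_range")
            rows.append(None if rec is None else
                        {"flag": rec["flag"], "tail_mean": rec["tail_mean"]})
        tails[key] = rows
    return {"peptides": names, "differences": table, "long_range": tails}


def strip_private(report: dict) -> dict:
    """Remove in-memory-only entries before JSON serialization."""
    return {k: v for k, v in report.items() if not k.startswith("_")}
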