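"""Posterior summarization: smoothed SIR surfaces, significance classes,
between-disease conditional correlations, and map export.

The standardized incidence ratio of area ``i`` and disease ``j`` is the
fitted relative risk ``SIR[i, j] = mu[i, j] / E[i, j] = exp(beta_j +
phi_ij)`` — the model-smoothed counterpart of the crude ratio of observed to
expected cases.  A posterior credible interval that excludes 1 flags an area
as significantly above or below the (covariate-adjusted) national level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .mcar import ChainOutput, MCARModelSpec, correlation_matrix

__all__ = [
    "SIRSurface",
    "CorrelationSummary",
    "sir_surface",
    "conditional_correlation",
    "percent_deviation",
    "export_maps",
]

CLASS_ABOVE = "above 1"
CLASS_BELOW = "below 1"
CLASS_NS = "not significant"


@dataclass(frozen=True)
class SIRSurface:
    """Per (area, disease) posterior SIR summary with significance class."""

    table: pd.DataFrame  # area, disease, sir_median, ci_low, ci_high, class
    level: float = 0.95

    def for_disease(self, disease: str) -> pd.DataFrame:
        return self.table[self.table["disease"] == disease].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class CorrelationSummary:
    """Posterior summary of between-disease conditional correlations at
    collocation, plus the spatial correlation parameter(s)."""

    table: pd.DataFrame       # pair, median, ci_low, ci_high
    rho: pd.DataFrame         # parameter, median, ci_low, ci_high

    def to_json(self, path) -> None:
        payload = {
            "correlations": self.table.to_dict(orient="records"),
            "rho": self.rho.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def sir_surface(
    chain: ChainOutput,
    E: np.ndarray,
    area_ids,
    diseases,
    level: float = 0.95,
) -> SIRSurface:
    """Posterior median and central credible interval of the fitted SIR.

    Per draw, ``SIR = mu / E``; areas with E = 0 are flagged (no SIR).  An
    area is classed above 1 iff its lower quantile exceeds 1, below 1 iff
    its upper quantile is under 1.
    """
    E = np.asarray(E, dtype=float)
    alpha = (1.0 - level) / 2.0
    rows = []
    for j, d in enumerate(diseases):
        for i, a in enumerate(area_ids):
            if E[i, j] == 0:
                rows.append((a, d, np.nan, np.nan, np.nan, "no expected cases"))
                continue
            sir = chain.mu[:, i, j] / E[i, j]
            lo, med, hi = np.quantile(sir, (alpha, 0.5, 1.0 - alpha))
            cls = CLASS_ABOVE if lo > 1 else CLASS_BELOW if hi < 1 else CLASS_NS
            rows.append((a, d, med, lo, hi, cls))
    table = pd.DataFrame(
        rows, columns=["area", "disease", "sir_median", "ci_low", "ci_high", "class"]
    )
    return SIRSurface(table=table, level=level)


def conditional_correlation(
    chain: ChainOutput,
    spec: MCARModelSpec,
    diseases=("AMI", "stroke", "AF"),
    level: float = 0.95,
) -> CorrelationSummary:
    """Between-disease conditional correlation at collocation.

    Per draw, ``corr_jk = Sigma_jk / sqrt(Sigma_jj Sigma_kk)`` from that
    draw's covariance matrix.  Under a shared spatial parameter (M2) this is
    exactly the collocated conditional correlation; for M1 the same summary
    is reported (the municipality-specific version is a separate,
    experimental computation).  M3 fixes all correlations to zero.
    """
    J = chain.beta.shape[1]
    alpha = (1.0 - level) / 2.0
    pairs = [(a, b) for a in range(J) for b in range(a + 1, J)]
    rows = []
    for p, (a, b) in enumerate(pairs):
        draws = np.empty(chain.n_draws)
        for s in range(chain.n_draws):
            R = correlation_matrix(chain.sigma_corr[s], J)
            Sig = R * np.outer(chain.sigma_sd[s], chain.sigma_sd[s])
            draws[s] = Sig[a, b] / np.sqrt(Sig[a, a] * Sig[b, b])
        lo, med, hi = np.quantile(draws, (alpha, 0.5, 1.0 - alpha))
        rows.append((f"{diseases[a]}-{diseases[b]}", med, lo, hi))
    table = pd.DataFrame(rows, columns=["pair", "median", "ci_low", "ci_high"])

    rho_rows = []
    if chain.rho.ndim == 1:
        lo, med, hi = np.quantile(chain.rho, (alpha, 0.5, 1.0 - alpha))
        rho_rows.append(("rho", med, lo, hi))
    else:
        for j in range(chain.rho.shape[1]):
            lo, med, hi = np.quantile(chain.rho[:, j], (alpha, 0.5, 1.0 - alpha))
            rho_rows.append((f"rho[{diseases[j]}]", med, lo, hi))
    rho = pd.DataFrame(rho_rows, columns=["parameter", "median", "ci_low", "ci_high"])
    return CorrelationSummary(table=table, rho=rho)


def conditional_correlation_by_area(
    chain: ChainOutput,
    graph,
    diseases=("AMI", "stroke", "AF"),
    level: float = 0.95,
    experimental: bool = False,
) -> pd.DataFrame:
    """Municipality-specific conditional correlation (disease-specific rho).

    With disease-specific spatial parameters the conditional covariance of
    the collocated effects at area i, given the neighbours, is
    ``sum_l A[j, l] A[k, l] / (rho_l d_i + 1 - rho_l)`` (the latent processes
    are conditionally independent across l with conditional variances
    ``1 / (rho_l d_i + 1 - rho_l)``).  Under a shared rho the area factor
    cancels and this reduces to the global summary.  EXPERIMENTAL: summary
    conventions for this quantity vary; guarded behind ``experimental=True``.
    """
    if not experimental:
        raise ValueError(
            "municipality-specific correlations are experimental; "
            "pass experimental=True to compute them"
        )
    J = chain.beta.shape[1]
    deg = graph.degrees().astype(float)
    alpha = (1.0 - level) / 2.0
    pairs = [(a, b) for a in range(J) for b in range(a + 1, J)]
    rows = []
    S = chain.n_draws
    for i, area in enumerate(graph.area_ids):
        draws = np.empty((S, len(pairs)))
        for s in range(S):
            R = correlation_matrix(chain.sigma_corr[s], J)
            Sig = R * np.outer(chain.sigma_sd[s], chain.sigma_sd[s])
            A = np.linalg.cholesky(Sig)
            rho = (np.full(J, chain.rho[s]) if chain.rho.ndim == 1
                   else chain.rho[s])
            w = 1.0 / (rho * deg[i] + 1.0 - rho)
            C = (A * w[None, :]) @ A.T
            for p, (a, b) in enumerate(pairs):
                draws[s, p] = C[a, b] / np.sqrt(C[a, a] * C[b, b])
        for p, (a, b) in enumerate(pairs):
            lo, med, hi = np.quantile(draws[:, p], (alpha, 0.5, 1.0 - alpha))
            rows.append((area, f"{diseases[a]}-{diseases[b]}", med, lo, hi))
    return pd.DataFrame(rows, columns=["area", "pair", "median", "ci_low", "ci_high"])


def percent_deviation(sir: float) -> int:
    """Signed percent deviation of an SIR from the national level.

    ``(sir - 1) * 100`` rounded to the nearest integer, e.g. SIR 0.76 is
    24% below and SIR 1.35 is 35% above the national rate.
    """
    if sir <= 0:
        raise ValueError("SIR must be positive")
    return int(round((sir - 1.0) * 100.0))


# ---------------------------------------------------------------------------
# Map export
# ---------------------------------------------------------------------------

def _fmt6(x: float) -> float:
    """Round to 6 significant digits for stable text round trips."""
    return float(f"{x:.6g}")


def export_maps(
    surface: SIRSurface,
    outdir,
    geometry: Optional[str] = None,
    id_property: str = "area_id",
    lattice_shape: Optional[tuple] = None,
) -> dict:
    """Write choropleth artifacts for an SIR surface.

    Without ``geometry``: a tidy CSV plus a lattice heat-grid PNG per disease
    (requires ``lattice_shape=(rows, cols)`` matching the area order).  With
    a GeoJSON ``geometry`` file: a GeoJSON whose features carry sir_median,
    ci bounds and significance class, plus a PNG per disease.

    Returns a manifest of written paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    csv_path = outdir / "sir_surface.csv"
    surface.to_csv(csv_path)
    manifest["csv"] = str(csv_path)

    diseases = list(dict.fromkeys(surface.table["disease"]))
    if geometry is not None:
        with open(geometry) as fh:
            gj = json.load(fh)
        by_area = {}
        for feat in gj["features"]:
            props = feat.get("properties") or {}
            by_area[props.get(id_property)] = feat
        unmatched = sorted(
            set(surface.table["area"].astype(str)) - set(map(str, by_area))
        )
        if unmatched:
            raise ValueError(f"areas missing from geometry: {unmatched}")
        for d in diseases:
            sub = surface.for_disease(d)
            feats = []
            for row in sub.itertuples(index=False):
                feat = json.loads(json.dumps(by_area[row.area]))  # deep copy
                feat["properties"] = dict(feat.get("properties") or {})
                feat["properties"].update(
                    {
                        "sir_median": _fmt6(row.sir_median),
                        "ci_low": _fmt6(row.ci_low),
                        "ci_high": _fmt6(row.ci_high),
                        "class": row[5],
                    }
                )
                feats.append(feat)
            path = outdir / f"sir_{d}.geojson"
            with open(path, "w") as fh:
                json.dump({"type": "FeatureCollection", "features": feats}, fh)
            manifest[f"geojson_{d}"] = str(path)
    if lattice_shape is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rows, cols = lattice_shape
        for d in diseases:
            sub = surface.for_disease(d)
            grid = np.asarray(sub["sir_median"], dtype=float).reshape(rows, cols)
            fig, ax = plt.subplots(figsize=(cols * 0.5, rows * 0.5))
            im = ax.imshow(grid, cmap="RdBu_r", vmin=0.7, vmax=1.3)
            fig.colorbar(im, ax=ax, label="SIR (posterior median)")
            ax.set_title(f"Smoothed SIR, {d}")
            ax.set_xticks([])
            ax.set_yticks([])
            path = outdir / f"sir_grid_{d}.png"
            fig.savefig(path, dpi=100, bbox_inches="tight")
            plt.close(fig)
            manifest[f"png_{d}"] = str(path)
    return manifest
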