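"""Synthetic tumor/normal RNA-seq cohort with planted ground truth.

Emulates the ingredients the downstream pipeline needs to be testable without
any data download: a class-imbalanced tumor/normal cohort for three RNA
classes (mRNA, lncRNA, miRNA), planted up/down differential expression,
zero-inflated molecules with condition-dependent dropout (the binary-branch
signal), planted miRNA->target regulatory trios with negative expression
correlation, candidate target sites partially covered by AGO CLIP intervals,
and right-censored survival times whose hazard depends on a planted module's
average expression.

Two noise models coexist:

* ordinary molecules follow a log-normal model: ``log2 x = mu + delta*1[tumor]
  + sigma * eps`` with molecule-specific ``mu`` and ``sigma``;
* planted regulatory trios (one miRNA plus one lncRNA and one mRNA target,
  opposed DE directions) use a truncated-Gaussian model with dispersion
  proportional to the group mean and a within-group correlation solved in
  closed form so that the POOLED (tumor+normal) Pearson correlation of each
  planted miRNA-target pair equals ``planted_edge_r`` in population (negative
  sign). Under a log-normal model with opposed fold changes the pooled
  raw-scale correlation cannot be held near a configured target, which is why
  the trios get their own model.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .matrix import ExpressionMatrix, concat_matrices

_TRIO_CV = 0.45  # coefficient of variation of planted-trio molecules
_BINARY_ON_TUMOR = 0.25  # ON rate of planted OFF-in-cancer molecules, tumor arm
_BINARY_ON_NORMAL = 0.97  # ... normal arm (survives the 10% normal-zero prefilter)


@dataclass(frozen=True)
class SimConfig:
    """Cohort layout and planted-signal parameters.

    All fractions are in [0, 1]. ``hazard_ratio`` is the multiplicative hazard
    of the module-low versus the module-high sample group (>1 means low module
    expression is the poor-prognosis group, as in breast carcinoma modules).
    """

    n_tumor: int = 100
    n_normal: int = 50
    n_mrna: int = 300
    n_lncrna: int = 160
    n_mirna: int = 80
    frac_de: float = 0.30
    log2_effect: float = 2.0
    frac_zero_inflated: float = 0.20
    n_planted_edges: int = 40
    planted_edge_r: float = 0.7
    n_decoy_candidates: int = 400
    clip_coverage: float = 0.8
    module_spec: tuple | None = None  # node ids; default: first 3 planted trios
    hazard_ratio: float = 3.0
    censor_rate: float = 0.2
    baseline_median_days: float = 1800.0
    n_cancer_genes: int = 60
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tumor", "n_normal", "n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_de", "frac_zero_inflated", "clip_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.planted_edge_r < 1.0:
            raise ValueError("planted_edge_r must be in [0, 1)")
        if self.n_planted_edges < 0 or self.n_planted_edges % 2:
            raise ValueError(
                "n_planted_edges must be a nonnegative even number: planted "
                "edges come in miRNA->(lncRNA, mRNA) trios so each planted "
                "miRNA satisfies the shared-miRNA network constraint"
            )
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")


@dataclass
class GroundTruthLedger:
    """What was planted, for downstream recovery checks."""

    de_molecules: dict  # id -> direction in {up, down, off_in_cancer}
    regulatory_edges: list  # (mirna_id, target_id) tuples
    prognostic_module: list  # node ids
    risk_groups: dict  # tumor sample id -> {low, high}
    seed: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["regulatory_edges"] = [list(e) for e in self.regulatory_edges]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLedger":
        d = json.loads(text)
        d["regulatory_edges"] = [tuple(e) for e in d["regulatory_edges"]]
        return cls(**d)


@dataclass
class SimulatedCohort:
    """Everything one pipeline run consumes, plus the ground truth."""

    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    clinical: pd.DataFrame  # sample_id, time_days, event
    clip_sites: pd.DataFrame  # transcript_id, start, end, source
    candidates: pd.DataFrame  # mirna_id, target_id, target_class, site_start, site_end
    gene_sets: dict  # name -> list of gene ids
    ledger: GroundTruthLedger
    config: SimConfig

    @property
    def combined(self) -> ExpressionMatrix:
        return concat_matrices([self.mrna, self.lncrna, self.mirna])


def _pooled_within_correlation(r_target, f, r_up, r_dn, cv):
    """Within-group correlation giving pooled correlation -r_target.

    The two pair members have tumor/normal mean ratios ``r_up`` and ``r_dn``
    (opposed directions) and dispersion proportional to the group mean
    (sd = cv * mean). With tumor fraction ``f`` and q = f(1-f), the pooled
    covariance decomposes into a within-group part and a between-group part;
    solving for the within-group correlation is a single linear equation.
    """
    q = f * (1.0 - f)
    d1, d2 = r_up - 1.0, r_dn - 1.0
    var1 = f * (cv * r_up) ** 2 + (1 - f) * cv**2 + q * d1**2
    var2 = f * (cv * r_dn) ** 2 + (1 - f) * cv**2 + q * d2**2
    wcov = cv**2 * (f * r_up * r_dn + (1 - f))
    rho = (-r_target * math.sqrt(var1 * var2) - q * d1 * d2) / wcov
    return float(np.clip(rho, -0.99, 0.99))


def _censor_scale(lam: np.ndarray, censor_rate: float) -> float:
    """Administrative-censoring horizon c with E[censored fraction] = censor_rate.

    Censoring times are U(0, c); for exponential survival with rate lam the
    per-sample censoring probability is (1 - exp(-lam c)) / (lam c), decreasing
    in c, so the horizon is found by bisection.
    """

    def frac(c):
        x = lam * c
        return float(np.mean((1.0 - np.exp(-x)) / x)) - censor_rate

    lo, hi = 1e-6, 1e12
    return brentq(frac, lo, hi, xtol=1e-6, rtol=1e-10)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort from one seeded RNG stream."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_s = cfg.n_tumor + cfg.n_normal
    samples = [f"T{i + 1:04d}" for i in range(cfg.n_tumor)] + [
        f"N{i + 1:04d}" for i in range(cfg.n_normal)
    ]
    is_tumor = np.array([s.startswith("T") for s in samples])
    condition = pd.Series(
        np.where(is_tumor, "tumor", "normal"), index=samples, name="condition"
    )

    ids = {
        "mRNA": [f"GENE{i + 1:05d}" for i in range(cfg.n_mrna)],
        "lncRNA": [f"LNC{i + 1:05d}" for i in range(cfg.n_lncrna)],
        "miRNA": [f"MIR{i + 1:04d}" for i in range(cfg.n_mirna)],
    }
    all_ids = ids["mRNA"] + ids["lncRNA"] + ids["miRNA"]
    cls_of = {m: c for c, lst in ids.items() for m in lst}

    # baseline log2 abundance and dispersion per molecule
    mu = {m: rng.uniform(4.0, 9.0) for m in all_ids}
    sigma = {m: rng.uniform(0.4, 0.8) for m in all_ids}

    # planted DE per class
    de_direction: dict[str, str] = {}
    for c in ("mRNA", "lncRNA", "miRNA"):
        n_de = int(round(cfg.frac_de * len(ids[c])))
        chosen = rng.choice(ids[c], size=n_de, replace=False)
        for m in chosen:
            de_direction[m] = "up" if rng.random() < 0.5 else "down"

    # planted regulatory trios among DE molecules
    n_trios = cfg.n_planted_edges // 2
    de_by_class = {
        c: [m for m in ids[c] if m in de_direction] for c in ids
    }
    for c, need in (("miRNA", n_trios), ("lncRNA", n_trios), ("mRNA", n_trios)):
        if len(de_by_class[c]) < need:
            raise ValueError(
                f"n_planted_edges={cfg.n_planted_edges} needs {need} DE {c} "
                f"molecules but frac_de yields only {len(de_by_class[c])}"
            )
    trio_mirnas = list(rng.choice(de_by_class["miRNA"], size=n_trios, replace=False))
    trio_lncs = list(rng.choice(de_by_class["lncRNA"], size=n_trios, replace=False))
    trio_mrnas = list(rng.choice(de_by_class["mRNA"], size=n_trios, replace=False))
    trios = list(zip(trio_mirnas, trio_lncs, trio_mrnas))
    trio_members = {m for t in trios for m in t}
    # opposed directions within a trio: targets mirror the miRNA
    for mir, lnc, gene in trios:
        d = de_direction[mir]
        anti = "down" if d == "up" else "up"
        de_direction[lnc] = anti
        de_direction[gene] = anti
    regulatory_edges = [(mir, lnc) for mir, lnc, _ in trios] + [
        (mir, gene) for mir, _, gene in trios
    ]

    # zero-inflated molecules (never trio members); DE ones become
    # OFF-in-cancer binary signals, null ones get a condition-independent rate
    zero_inflated: set[str] = set()
    for c in ids:
        pool = [m for m in ids[c] if m not in trio_members]
        n_zi = min(int(round(cfg.frac_zero_inflated * len(ids[c]))), len(pool))
        zero_inflated.update(rng.choice(pool, size=n_zi, replace=False))
    binary_de = {m for m in zero_inflated if m in de_direction}
    for m in binary_de:
        de_direction[m] = "off_in_cancer"

    # --- expression values ---------------------------------------------------
    values = np.empty((len(all_ids), n_s))
    row_of = {m: i for i, m in enumerate(all_ids)}
    f_t = cfg.n_tumor / n_s
    r_up = 2.0**cfg.log2_effect
    r_dn = 2.0**-cfg.log2_effect
    rho_w = _pooled_within_correlation(cfg.planted_edge_r, f_t, r_up, r_dn, _TRIO_CV)
    a = abs(rho_w)
    mir_sign = 1.0 if rho_w >= 0 else -1.0

    for m in all_ids:
        if m in trio_members:
            continue
        shift = 0.0
        if m in de_direction and m not in binary_de:
            shift = cfg.log2_effect if de_direction[m] == "up" else -cfg.log2_effect
        log2x = mu[m] + shift * is_tumor + sigma[m] * rng.standard_normal(n_s)
        x = 2.0**log2x
        if m in zero_inflated:
            if m in binary_de:
                on_rate = np.where(is_tumor, _BINARY_ON_TUMOR, _BINARY_ON_NORMAL)
                x = x * (rng.random(n_s) < on_rate)
            else:
                x = x * (rng.random(n_s) < rng.uniform(0.90, 0.97))
        values[row_of[m]] = x

    for mir, lnc, gene in trios:
        z = rng.standard_normal(n_s)
        d_mir = de_direction[mir]
        for m in (mir, lnc, gene):
            eps = rng.standard_normal(n_s)
            g = math.sqrt(a) * z + math.sqrt(1.0 - a) * eps
            if m == mir:
                g = mir_sign * g
            ratio = r_up if de_direction[m] == "up" else r_dn
            group_mean = 2.0 ** mu[m] * np.where(is_tumor, ratio, 1.0)
            values[row_of[m]] = np.maximum(0.0, group_mean * (1.0 + _TRIO_CV * g))
        del d_mir

    matrices = {}
    for c in ids:
        rows = [row_of[m] for m in ids[c]]
        matrices[c] = ExpressionMatrix(
            pd.DataFrame(values[rows], index=ids[c], columns=samples),
            pd.Series(c, index=ids[c], name="class"),
            condition,
        )

    # --- prognostic module and survival --------------------------------------
    if cfg.module_spec is not None:
        module = list(cfg.module_spec)
        unknown = [m for m in module if m not in cls_of]
        if unknown:
            raise ValueError(f"module_spec references unknown ids: {unknown}")
    elif trios:
        module = [m for t in trios[: min(3, len(trios))] for m in t]
    else:  # null cohorts: an arbitrary (signal-free) module
        module = list(rng.choice(all_ids, size=min(9, len(all_ids)), replace=False))

    tumor_cols = np.flatnonzero(is_tumor)
    mod_rows = np.array([row_of[m] for m in module])
    mod_vals = values[np.ix_(mod_rows, tumor_cols)]
    sd = mod_vals.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    zscores = (mod_vals - mod_vals.mean(axis=1, keepdims=True)) / sd[:, None]
    score = zscores.mean(axis=0)
    low = score < np.median(score)  # module-low = poor-prognosis group
    lam0 = math.log(2.0) / cfg.baseline_median_days
    lam = lam0 * np.where(low, cfg.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    if cfg.censor_rate > 0:
        c_max = _censor_scale(lam, cfg.censor_rate)
        t_cens = rng.uniform(0.0, c_max, size=len(lam))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(lam), dtype=int)
    tumor_ids = [samples[i] for i in tumor_cols]
    clinical = pd.DataFrame(
        {"sample_id": tumor_ids, "time_days": time, "event": event}
    )
    risk_groups = {
        s: ("low" if lo else "high") for s, lo in zip(tumor_ids, low)
    }

    # --- candidate target sites and CLIP intervals ----------------------------
    site_counter: dict[str, int] = {}

    def next_site(target):
        k = site_counter.get(target, 0)
        site_counter[target] = k + 1
        start = 30 + 40 * k  # disjoint grid: CLIP cover is exact by construction
        return start, start + 7

    cand_rows = []
    for mir, target in regulatory_edges:
        for _ in range(int(rng.integers(1, 3))):  # 1-2 sites per true pair
            s, e = next_site(target)
            cand_rows.append((mir, target, cls_of[target], s, e, True))
    null_mirnas = [
        m for m in ids["miRNA"] if m not in de_direction and m not in trio_members
    ]
    null_targets = [
        m
        for m in ids["mRNA"] + ids["lncRNA"]
        if m not in de_direction and m not in trio_members
    ]
    decoy_pairs: set[tuple] = set()
    guard = 0
    while len(decoy_pairs) < cfg.n_decoy_candidates:
        guard += 1
        if guard > 100 * cfg.n_decoy_candidates:
            raise ValueError("cannot draw enough unique decoy pairs; too few null molecules")
        pair = (
            str(rng.choice(null_mirnas)),
            str(rng.choice(null_targets)),
        )
        decoy_pairs.add(pair)
    for mir, target in sorted(decoy_pairs):
        s, e = next_site(target)
        cand_rows.append((mir, target, cls_of[target], s, e, False))
    candidates = pd.DataFrame(
        cand_rows,
        columns=["mirna_id", "target_id", "target_class", "site_start", "site_end", "_planted"],
    )

    n_cov = int(round(cfg.clip_coverage * len(candidates)))
    order = np.concatenate(
        [
            np.flatnonzero(candidates["_planted"].values),
            np.flatnonzero(~candidates["_planted"].values),
        ]
    )
    covered = candidates.iloc[order[:n_cov]]
    clip_rows = [
        (row.target_id, row.site_start + 1, row.site_start + 4,
         "AGO1" if rng.random() < 0.5 else "AGO2")
        for row in covered.itertuples()
    ]
    # background AGO peaks placed in inter-site gaps (overlap nothing)
    for target, k in list(site_counter.items())[:: 5]:
        start = 30 + 40 * k + 15
        clip_rows.append((target, start, start + 5, "AGO2"))
    clip_sites = pd.DataFrame(
        clip_rows, columns=["transcript_id", "start", "end", "source"]
    )
    candidates = candidates.drop(columns="_planted")

    # --- planted cancer-gene catalog (half DE, half background) --------------
    de_genes = [m for m in ids["mRNA"] if m in de_direction]
    bg_genes = [m for m in ids["mRNA"] if m not in de_direction]
    n_half = cfg.n_cancer_genes // 2
    cancer = list(rng.choice(de_genes, size=min(n_half, len(de_genes)), replace=False))
    cancer += list(
        rng.choice(bg_genes, size=min(cfg.n_cancer_genes - len(cancer), len(bg_genes)),
                   replace=False)
    )

    ledger = GroundTruthLedger(
        de_molecules=dict(sorted(de_direction.items())),
        regulatory_edges=regulatory_edges,
        prognostic_module=module,
        risk_groups=risk_groups,
        seed=cfg.seed,
    )
    for m in ledger.de_molecules:
        assert m in cls_of
    return SimulatedCohort(
        mrna=matrices["mRNA"],
        lncrna=matrices["lncRNA"],
        mirna=matrices["miRNA"],
        clinical=clinical,
        clip_sites=clip_sites,
        candidates=candidates,
        gene_sets={"cancer_genes": sorted(cancer)},
        ledger=ledger,
        config=cfg,
    )


def write_dataset(cohort: SimulatedCohort, out_dir) -> dict:
    """Serialize a cohort as TSV/BED/JSON text files; return a file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cohort.config.seed, "files": {}}

    def record(name, n_rows):
        manifest["files"][name] = {"rows": int(n_rows)}

    for name, mat in (("mrna", cohort.mrna), ("lncrna", cohort.lncrna),
                      ("mirna", cohort.mirna)):
        p = out / f"{name}.tsv"
        mat.values.rename_axis("molecule_id").to_csv(p, sep="\t")
        record(p.name, mat.values.shape[0])
    anno = pd.concat(
        [m.molecule_class for m in (cohort.mrna, cohort.lncrna, cohort.mirna)]
    )
    anno.rename("class").rename_axis("molecule_id").to_csv(
        out / "annotation.tsv", sep="\t"
    )
    record("annotation.tsv", len(anno))
    cond = cohort.mrna.sample_condition
    cond.rename("condition").rename_axis("sample_id").to_csv(
        out / "conditions.tsv", sep="\t"
    )
    record("conditions.tsv", len(cond))
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    record("clinical.tsv", len(cohort.clinical))
    with open(out / "clip_sites.bed", "w") as fh:  # BED3+1, 0-based half-open
        for row in cohort.clip_sites.itertuples(index=False):
            fh.write(f"{row.transcript_id}\t{row.start}\t{row.end}\t{row.source}\n")
    record("clip_sites.bed", len(cohort.clip_sites))
    cohort.candidates.to_csv(out / "target_candidates.tsv", sep="\t", index=False)
    record("target_candidates.tsv", len(cohort.candidates))
    for name, genes in cohort.gene_sets.items():
        p = out / f"{name}.txt"
        p.write_text("".join(g + "\n" for g in genes))
        record(p.name, len(genes))
    (out / "ground_truth.json").write_text(cohort.ledger.to_json())
    record("ground_truth.json", len(cohort.ledger.de_molecules))
    (out / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(cohort.config), indent=1, sort_keys=True)
    )
    record("sim_config.json", 1)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_dataset(in_dir) -> SimulatedCohort:
    """Load a cohort written by :func:`write_dataset` (exact round trip)."""
    d = Path(in_dir)
    anno = pd.read_csv(d / "annotation.tsv", sep="\t", index_col=0)["class"].rename_axis(None)
    cond = pd.read_csv(d / "conditions.tsv", sep="\t", index_col=0)["condition"].rename_axis(None)
    mats = {}
    for name in ("mrna", "lncrna", "mirna"):
        vals = pd.read_csv(d / f"{name}.tsv", sep="\t", index_col=0).rename_axis(None)
        mats[name] = ExpressionMatrix(vals, anno.loc[vals.index], cond)
    clip = pd.read_csv(
        d / "clip_sites.bed", sep="\t", header=None,
        names=["transcript_id", "start", "end", "source"],
    )
    cfg = SimConfig(**{
        k: (tuple(v) if k == "module_spec" and v is not None else v)
        for k, v in json.loads((d / "sim_config.json").read_text()).items()
    })
    gene_sets = {}
    for p in sorted(d.glob("*.txt")):
        gene_sets[p.stem] = p.read_text().split()
    return SimulatedCohort(
        mrna=mats["mrna"],
        lncrna=mats["lncrna"],
        mirna=mats["mirna"],
        clinical=pd.read_csv(d / "clinical.tsv", sep="\t"),
        clip_sites=clip,
        candidates=pd.read_csv(d / "target_candidates.tsv", sep="\t"),
        gene_sets=gene_sets,
        ledger=GroundTruthLedger.from_json((d / "ground_truth.json").read_text()),
        config=cfg,
    )
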