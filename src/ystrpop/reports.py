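"""Tabular report builders: the analysis's standard output tables.

Four report shapes mirror the conventional presentation of Y-STR
phylogeography results:

* per-population diversity summary (n, h, HD±SD, MPD±SD, AMD, variance,
  expansion age in KYA);
* combined distance matrix (PiX diagonal, PiXY above, (δμ)² below);
* founder/dating table (cluster n, ρ and TD TMRCAs with SDs, summary row);
* group-comparison AMOVA table (fixation index of a focal group against
  each other group).
"""

from __future__ import annotations

import pandas as pd

from .dating import DatingParams, founder_age_summary, group_expansion_age, rho_statistic, \
    rho_to_age, td_statistic
from .distances import amova, combined_distance_table
from .diversity import avg_mutational_distance, diversity_summary, modal_haplotype
from .mjnetwork import FounderCluster
from .strdata import Dataset, STRHaplotype

__all__ = [
    "diversity_table",
    "combined_distance_table",
    "founder_table",
    "group_comparison_table",
    "write_tsv",
]


def diversity_table(dataset: Dataset, ref: STRHaplotype | None = None,
                    metric: str = "allele", params: DatingParams | None = None,
                    with_age: bool = True) -> pd.DataFrame:
    """Per-population diversity summary; ``ref`` is the AMD reference
    haplotype (e.g. a focal-group modal haplotype)."""
    params = params or DatingParams()
    rows = []
    for pop in dataset.populations:
        s = diversity_summary(pop, ref=ref, metric=metric)
        row = {
            "population": s.name, "group": pop.group, "n": s.n, "h": s.h,
            "HD": round(s.hd, 4), "HD_sd": round(s.hd_sd, 4),
            "MPD": round(s.mpd, 4), "MPD_sd": round(s.mpd_sd, 4),
            "AMD": None if s.amd is None else round(s.amd, 2),
            "variance": round(s.variance, 2),
        }
        if with_age and pop.n >= 2:
            age = group_expansion_age(pop, params)
            row["age_kya"] = round(age.age_years / 1000.0, 2)
            row["age_sd_kya"] = round(age.sd_years / 1000.0, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def founder_table(clusters: list[FounderCluster], params: DatingParams | None = None) -> pd.DataFrame:
    """Founder-analysis table: one row per cluster plus an unweighted
    summary row (mean age, mean SD) for each dating method."""
    params = params or DatingParams()
    rows, rho_ests, td_ests = [], [], []
    for cl in clusters:
        rho, sd = rho_statistic(cl)
        est_r = rho_to_age(rho, sd, params)
        est_t = td_statistic(cl, cl.root, params)
        rho_ests.append(est_r)
        td_ests.append(est_t)
        rows.append({
            "n": cl.n, "rho": round(rho, 4),
            "tmrca_rho_years": round(est_r.age_years),
            "sd_rho_years": round(est_r.sd_years),
            "asd": round(est_t.statistic, 4),
            "tmrca_td_years": round(est_t.age_years),
            "sd_td_years": round(est_t.sd_years),
        })
    if rows:
        sr, st = founder_age_summary(rho_ests), founder_age_summary(td_ests)
        rows.append({
            "n": sum(cl.n for cl in clusters), "rho": None,
            "tmrca_rho_years": round(sr.age_years), "sd_rho_years": round(sr.sd_years),
            "asd": None,
            "tmrca_td_years": round(st.age_years), "sd_td_years": round(st.sd_years),
        })
    return pd.DataFrame(rows)


def group_comparison_table(dataset: Dataset, focal_group: str,
                           metric: str = "allele", statistic: str = "phi_st") -> pd.DataFrame:
    """Fixation index of the focal group's populations against each other
    group, from a two-group AMOVA per comparison.

    ``statistic`` selects which Φ is reported ("phi_st" default, "phi_ct"
    available): a single printed "Fst" per comparison does not disambiguate
    the two, so both designs are exposed.
    """
    groups = sorted({p.group for p in dataset.populations})
    if focal_group not in groups:
        raise ValueError(f"no populations in group {focal_group!r}")
    focal_pops = [p.name for p in dataset.populations if p.group == focal_group]
    rows = []
    for other in groups:
        if other == focal_group:
            continue
        other_pops = [p.name for p in dataset.populations if p.group == other]
        sub = dataset.subset(focal_pops + other_pops)
        grouping = {n: focal_group for n in focal_pops}
        grouping.update({n: other for n in other_pops})
        res = amova(sub, grouping=grouping, metric=metric)
        rows.append({
            "comparison": f"{focal_group} vs {other}",
            "fixation_index": round(getattr(res, statistic), 5),
            "phi_st": round(res.phi_st, 5),
            "phi_ct": round(res.phi_ct, 5),
            "phi_sc": round(res.phi_sc, 5),
        })
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None,
              index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)
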