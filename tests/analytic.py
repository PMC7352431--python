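"""Closed-form expectations used as independent oracles.

Everything here is derived analytically from the generator's documented
distributions and the cascade's documented thresholds — no call into the
cascade or simulator code paths being checked.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def hwe_probs(p: float) -> tuple[float, float, float]:
    q = 1.0 - p
    return (q * q, 2.0 * p * q, p * p)


def seg_pass_prob_independent(ped, p: float) -> float:
    """Per-member product: genotypes i.i.d. HWE(p), roles constrain
    cases to dosage >= 1 and controls to dosage 0."""
    g0, g1, g2 = hwe_probs(p)
    prob = 1.0
    for m in ped:
        if not m.sample_available:
            continue
        if m.role == "case":
            prob *= g1 + g2
        elif m.role == "control":
            prob *= g0
    return prob


def seg_pass_prob_genedrop(ped, p: float) -> float:
    """Exact pass probability under founder-HWE + Mendelian gene drop
    for a two-founder pedigree: enumerate founder genotype pairs;
    children are conditionally independent given the founders."""
    founders = [m for m in ped if m.father is None]
    children = [m for m in ped if m.father is not None]
    assert len(founders) == 2
    fa, mo = founders
    gp = hwe_probs(p)
    total = 0.0
    for gf in range(3):
        for gm in range(3):
            w = gp[gf] * gp[gm]
            geno = {fa.id: gf, mo.id: gm}
            ok = True
            for f in founders:
                if not f.sample_available:
                    continue
                if f.role == "case" and geno[f.id] == 0:
                    ok = False
                if f.role == "control" and geno[f.id] > 0:
                    ok = False
            if not ok:
                continue
            p_zero = (1.0 - gf / 2.0) * (1.0 - gm / 2.0)
            for c in children:
                if not c.sample_available:
                    continue
                if c.role == "case":
                    w *= 1.0 - p_zero
                elif c.role == "control":
                    w *= p_zero
            total += w
    return total


def vote_pass_prob(p_del: float, p_missing: float, min_calls: int = 5,
                   n_tools: int = 10) -> float:
    """P(consensus vote passes): availability Binomial(10, 1 - miss),
    deleterious calls Binomial(n_avail, p_del), pass iff n_avail >= 5
    and 5*k >= 3*n_avail (the exact float comparison k/n >= 0.6)."""
    total = 0.0
    for n_avail in range(min_calls, n_tools + 1):
        pa = stats.binom.pmf(n_avail, n_tools, 1.0 - p_missing)
        for k in range(n_avail + 1):
            if 5 * k >= 3 * n_avail:
                total += pa * stats.binom.pmf(k, n_avail, p_del)
    return total


def conservation_pass_prob(cfg, latent: bool) -> float:
    """P(all available conservation scores pass, at least one present)."""
    miss = cfg.missing_rates
    q_gerp = 1.0 - stats.norm.cdf(2.0, *(cfg.gerp_del if latent else cfg.gerp_null))
    a, b = cfg.phastcons_del if latent else cfg.phastcons_null
    q_pc = 1.0 - stats.beta.cdf(0.3, a, b)
    q_pp = 1.0 - stats.norm.cdf(3.0, *(cfg.phylop_del if latent else cfg.phylop_null))
    terms = [
        (miss["gerp"], q_gerp),
        (miss["phastcons"], q_pc),
        (miss["phylop"], q_pp),
    ]
    all_ok = math.prod(m + (1.0 - m) * q for m, q in terms)
    all_missing = math.prod(m for m, _ in terms)
    return all_ok - all_missing


def cadd_pass_prob(cfg, latent: bool) -> float:
    q = 1.0 - stats.norm.cdf(10.0, *(cfg.cadd_del if latent else cfg.cadd_null))
    return (1.0 - cfg.missing_rates["cadd"]) * q


def background_survival_prob(ped, cfg, n_grid: int = 4001) -> float:
    """Expected per-variant probability of surviving the whole default
    cascade, for background variants from the given generator config."""
    # quality: QUAL ~ U(qual_range) strictly > 20, every sampled depth
    # Poisson(depth_mean) strictly > 5, caller pass Bernoulli
    lo, hi = cfg.qual_range
    p_qual = (hi - 20.0) / (hi - lo)
    n_sampled = len(ped.genotyped_ids())
    p_depth = (1.0 - stats.poisson.cdf(5, cfg.depth_mean)) ** n_sampled
    p_quality = p_qual * p_depth * cfg.p_caller_pass

    # rarity and segregation are coupled through the allele frequency
    u = np.linspace(*cfg.log10_af_range, n_grid)
    af = 10.0 ** u
    m1 = cfg.missing_rates["maf_1kg"]
    m2 = cfg.missing_rates["maf_exac"]
    p_rare = np.where(af <= 0.001, 1.0, m1 * m2)
    seg = (
        seg_pass_prob_genedrop if cfg.mendelian else seg_pass_prob_independent
    )
    p_seg = np.array([seg(ped, float(a)) for a in af])
    p_rare_seg = float(np.trapezoid(p_rare * p_seg, u) / (u[-1] - u[0]))

    # consequence class eligible for the vote stage
    p_csq = sum(cfg.consequence_probs[c] for c in ("missense", "nonsense", "splice"))

    # CADD / conservation / vote share the latent deleteriousness flag
    pi = cfg.p_latent_deleterious
    m_pred = cfg.missing_rates["predictor"]
    p_scores = 0.0
    for latent, w in ((True, pi), (False, 1.0 - pi)):
        p_del = cfg.predictor_concordance if latent else 1.0 - cfg.predictor_concordance
        p_scores += (
            w
            * cadd_pass_prob(cfg, latent)
            * conservation_pass_prob(cfg, latent)
            * vote_pass_prob(p_del, m_pred)
        )

    return p_quality * p_rare_seg * p_csq * p_scores
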