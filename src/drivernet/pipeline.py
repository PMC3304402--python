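"""End-to-end convenience layer: cohort -> seeds -> resampled driver-network."""

from __future__ import annotations

import logging

from .expansion import DriverNetwork, resampled_driver_network
from .network_space import NetworkSpace
from .omics_data import (
    OmicsCohort,
    average_cna_score,
    cna_expression_correlation,
    discretize_cna,
)
from .seed_selection import SeedSet, select_seeds

log = logging.getLogger(__name__)


def select_cohort_seeds(
    cohort: OmicsCohort,
    subtype: str,
    top_frac_cna: float = 0.05,
    top_frac_corr: float = 0.10,
    mode: str = "absolute",
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
    corr_absolute: bool = False,
) -> SeedSet:
    """Seed genes for one subtype from a cohort's CNA and expression data.

    Discretises copy number if needed, averages calls over the subtype's
    samples, correlates calls with expression pooling all subtypes, and
    intersects the two top-ranked lists.
    """
    disc = cohort.cna if cohort.cna.is_discrete else discretize_cna(
        cohort.cna, gain_threshold, loss_threshold)
    scores = average_cna_score(disc, cohort.labels, subtype,
                               samples=cohort.shared_samples)
    corrs = cna_expression_correlation(cohort, gain_threshold=gain_threshold,
                                       loss_threshold=loss_threshold)
    seeds = select_seeds(scores, corrs, top_frac_cna=top_frac_cna,
                         top_frac_corr=top_frac_corr, mode=mode,
                         corr_absolute=corr_absolute, subtype=subtype)
    log.info("%s: %d seed gene(s) selected over %d-gene universe",
             subtype, len(seeds), len(scores.index.intersection(corrs.index)))
    return seeds


def find_driver_network(
    cohort: OmicsCohort,
    net: NetworkSpace,
    subtype: str,
    seeds: SeedSet | set | None = None,
    sample_frac: float = 0.8,
    reps: int = 1000,
    membership_min: float = 0.5,
    rng_seed: int = 0,
    **kwargs,
) -> DriverNetwork:
    """Full pipeline: (select or accept) seeds, then resampled expansion.

    ``seeds`` may come from another cohort's selection; when omitted they are
    selected from this cohort at the default cutoffs.
    """
    if seeds is None:
        seeds = select_cohort_seeds(cohort, subtype)
    return resampled_driver_network(
        seeds, net, cohort, subtype, sample_frac=sample_frac, reps=reps,
        membership_min=membership_min, rng_seed=rng_seed, **kwargs)
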