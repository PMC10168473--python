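"""End-to-end differential pipeline and its run configuration.

Stages, in order: PIS per sample -> Gaussian smoothing -> MA
normalization to a reference sample -> residual of condition means ->
HMM segmentation -> replicate-based significance -> domain filtering.
Each run writes its resolved configuration next to its outputs, and
every output file carries a header with the package version and a
configuration hash so artifacts are traceable to their parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import io as dio
from .genome import BinnedGenome
from .manorm import normalize_pair
from .pis import compute_pis_genome, residual, smooth_pis
from .segmentation import decode, fit_hmm
from .significance import build_null, delta_pis, filter_domains, significance_track

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Defaults are the method's canonical operating point: 50 kb bins,
    smoothing sigma of 3 bins, 15-85% background percentile window,
    4 HMM states, significance-score cap 20 and domain-score
    threshold 2.
    """

    bin_size: int = 50_000
    sigma: float = 3.0
    lo_pct: float = 15.0
    hi_pct: float = 85.0
    n_states: int = 4
    seed: int = 13
    threshold: float = 2.0
    chroms: dict = field(default_factory=dict)  # name -> length (bp)
    gaps: str | None = None
    samples: dict = field(default_factory=dict)  # id -> {oe: {chrom: path}, compartments: path}
    condition1: list = field(default_factory=list)
    condition2: list = field(default_factory=list)
    reference: str | None = None
    outdir: str = "daric_out"

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (not I/O locations), so runs of
        the same analysis in different directories stamp identically."""
        params = {k: v for k, v in asdict(self).items()
                  if k not in ("samples", "gaps", "outdir")}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:10]

    def header(self) -> list[str]:
        return [f"daric v{__version__} config={self.config_hash}"]

    def genome(self) -> BinnedGenome:
        if not self.chroms:
            raise ValueError("config must list chromosomes and lengths")
        names = list(self.chroms)
        genome = BinnedGenome(tuple(names), tuple(self.chroms[c] for c in names),
                              self.bin_size)
        if self.gaps:
            genome = dio.read_gaps(self.gaps, genome)
        return genome


def _sample_pis(config: RunConfig, sample: str, genome: BinnedGenome):
    spec = config.samples[sample]
    comp_path = spec["compartments"]
    if not os.path.exists(comp_path):
        raise FileNotFoundError(f"compartment file not found: {comp_path}")
    comps = dio.read_compartments(comp_path, genome,
                                  orientation=spec.get("orientation", "as_is"))
    oes = []
    for chrom, path in spec["oe"].items():
        if not os.path.exists(path):
            raise FileNotFoundError(f"O/E dump file not found: {path}")
        oes.append(dio.read_oe_dump(path, chrom, genome))
    track = compute_pis_genome(oes, comps, genome, sample=sample)
    return smooth_pis(track, config.sigma)


def run_pipeline(config: RunConfig) -> dict:
    """Execute pis -> norm -> residual -> diff -> test and write artifacts.

    Returns a dict of output paths. Requires two conditions of samples;
    significance testing runs when both conditions have two replicates.
    """
    os.makedirs(config.outdir, exist_ok=True)
    header = config.header()
    genome = config.genome()
    outputs: dict[str, str] = {}

    logger.info("stage pis: computing smoothed PIS for %d samples",
                len(config.samples))
    pis = {s: _sample_pis(config, s, genome) for s in config.samples}
    reference = config.reference or config.condition1[0]

    logger.info("stage norm: normalizing to reference %s", reference)
    normalized = {}
    for s, track in pis.items():
        if s == reference:
            normalized[s] = track
        else:
            normalized[s], model = normalize_pair(pis[reference], track,
                                                  config.lo_pct, config.hi_pct)
            mpath = os.path.join(config.outdir, f"norm_model_{s}.json")
            with open(mpath, "w") as fh:
                json.dump(model.to_dict(), fh, indent=1)
    for s, track in normalized.items():
        p = os.path.join(config.outdir, f"pis_{s}.bedGraph")
        dio.write_track(track, p, header=header)
        outputs[f"pis_{s}"] = p

    logger.info("stage residual: condition means and ΔPIS")
    c1 = [normalized[s] for s in config.condition1]
    c2 = [normalized[s] for s in config.condition2]
    delta = delta_pis(c1, c2)
    respath = os.path.join(config.outdir, "residual.bedGraph")
    dio.write_track(delta, respath, header=header)
    outputs["residual"] = respath

    logger.info("stage diff: %d-state HMM segmentation", config.n_states)
    model = fit_hmm(delta, n_states=config.n_states, seed=config.seed)
    seg = decode(model, delta)
    with open(os.path.join(config.outdir, "hmm.json"), "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)

    if len(c1) == 2 and len(c2) == 2:
        logger.info("stage test: empirical null from replicates")
        null = build_null(c1, c2)
        scores = significance_track(delta, null)
        seg = filter_domains(seg, scores, threshold=config.threshold)
        spath = os.path.join(config.outdir, "scores.bedGraph")
        dio.write_track(scores, spath, header=header)
        outputs["scores"] = spath
    else:
        logger.warning("significance skipped: need 2+2 replicates, got %d+%d",
                       len(c1), len(c2))

    dpath = os.path.join(config.outdir, "domains.bed")
    dio.write_domains(seg, dpath, header=header)
    outputs["domains"] = dpath
    sig = [d for d in seg.domains if d.significant]
    if sig:
        from .segmentation import DomainSegmentation

        sigpath = os.path.join(config.outdir, "significant_domains.bed")
        dio.write_domains(DomainSegmentation(genome, sig, seg.emissions), sigpath,
                          header=header)
        outputs["significant_domains"] = sigpath

    cfgpath = os.path.join(config.outdir, "run_config.yaml")
    config.to_yaml(cfgpath)
    outputs["config"] = cfgpath
    logger.info("pipeline complete: %d outputs in %s", len(outputs), config.outdir)
    return outputs
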