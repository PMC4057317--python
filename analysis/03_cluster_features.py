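"""Pool all included tumor voxels and ISODATA-cluster each feature vector.

Voxels from every animal and time point are pooled, normalized to zero mean
and unit SD per feature, and clustered with the split/merge loop; label
volumes and centroid tables are written per feature vector.
"""
import argparse

from hifuseg.pipeline import RunConfig, stage_cluster
from hifuseg.isodata import spec_key


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default="analysis/config_demo.yaml")
    parser.add_argument("--out", default="results/demo")
    parser.add_argument("--seed", type=int, default=None)
    args = parser.parse_args()

    cfg = RunConfig.from_yaml(args.config)
    if args.seed is not None:
        cfg.seed = args.seed
    for i, spec in enumerate(cfg.feature_vectors):
        model = stage_cluster(cfg, args.out, spec, i)
        sizes = model.sizes
        print(f"{spec_key(spec):14s}: {model.n_clusters:3d} clusters over "
              f"{model.labels.shape[0]} voxels "
              f"(smallest {sizes.min()}, largest {sizes.max()}; "
              f"converged={model.converged})")


if __name__ == "__main__":
    main()
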