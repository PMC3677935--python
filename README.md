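# mixentropy

Conditional-entropy quantification of disorder in multicomponent lattice
and particle systems — mixing and demixing in binary fluids and lipid
membranes, order–disorder transitions in spin models.

## The problem

How mixed is a two-component fluid membrane, halfway through demixing?
Global measures fail here: the mean-field (composition) entropy of an
equimolar mixture is ln 2 no matter how ordered the configuration is, and
the classical subregion estimate — divide the box into m² regions, average
the regions' composition entropies — depends strongly on m and is blind to
order on scales below the region size, exactly the regime where domains
first form.

`mixentropy` instead estimates the Shannon entropy per particle as a
**conditional entropy**:

    S  ≈  H(σᵢ | bᵢ)  =  H(σᵢ, bᵢ) − H(bᵢ)

where σᵢ is the type of particle i and bᵢ is a discrete state of its
neighbourhood, restricted to the **upper half-space** so that each pair is
counted once.  The estimate is bounded by 0 (fully demixed) and the ideal
mixing entropy −Σ x_c ln x_c (fully mixed), captures local correlations,
and is nearly independent of how the neighbourhood is discretised.  All
entropies are in nats (k_B omitted), computed from raw pooled frequencies.

The package provides:

* the conditional estimator for lattices (`conditional_entropy_lattice`,
  half-plane neighbourhood within a cut-off radius) and for particle
  snapshots (`conditional_entropy_particles` with three neighbourhood
  discretisations: NB-cutoff, NB-shell, NB-weight);
* comparison estimators: mean-field, Bethe (1D), Kikuchi cluster-variation
  (2D square lattice), subregion/binned Shannon entropy;
* exact references: Onsager's 2D Ising entropy, the 1D transfer matrix,
  exhaustive enumeration of small lattices;
* simulators that generate all validation data: Ising Monte-Carlo
  (Glauber and magnetisation-conserving Kawasaki dynamics) and a 2D
  Brownian-dynamics binary Lennard-Jones mixture with mixing
  (purely repulsive, WCA-truncated) and demixing (same-type attraction)
  interaction sets, plus deterministic mixed/demixed/clustered synthetic
  configurations;
* I/O: a plain-text lattice frame format, extended-XYZ trajectories,
  delimited tables, and a GRO adapter selecting one bead per lipid so
  coarse-grained membrane snapshots can be analysed.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
import numpy as np
from mixentropy import (IsingParams, NeighbourhoodSpec,
                        conditional_entropy_lattice, kikuchi_entropy,
                        mean_field_entropy, onsager_entropy, simulate_glauber,
                        generate_mixed, generate_demixed, generate_clustered,
                        conditional_entropy_particles, binned_shannon_entropy)
from mixentropy.particle_sim import box_for_density

# --- lattice: Ising model at T = 3.0 (above T_c ~ 2.269) -----------------
ens = simulate_glauber(IsingParams(L=64, T=3.0, n_sweeps=2000, seed=0))
print("mean-field :", round(mean_field_entropy(ens).value, 4))
print("Kikuchi    :", round(kikuchi_entropy(ens).value, 4))
print("conditional:", round(conditional_entropy_lattice(ens, np.sqrt(2)).value, 4))
print("Onsager    :", round(onsager_entropy(3.0), 4))

# --- particles: three n = 10^4 snapshots ---------------------------------
n, box = 10000, box_for_density(10000)
spec = NeighbourhoodSpec("cutoff", k=6)
for name, snap in [("mixed   ", generate_mixed(n, box, seed=0)),
                   ("demixed ", generate_demixed(n, box, seed=0)),
                   ("clustered", generate_clustered(n, box, 180, 3.0, seed=0))]:
    cond = conditional_entropy_particles(snap, spec)
    binned = binned_shannon_entropy(snap, 10)
    print(f"{name}  conditional={cond.value:.4f}  binned(m=10)={binned.value:.4f}")
```

Output:

```
mean-field : 0.6931
Kikuchi    : 0.5432
conditional: 0.5444
Onsager    : 0.5434
mixed      conditional=0.6896  binned(m=10)=0.6880
demixed    conditional=0.0085  binned(m=10)=0.0000
clustered  conditional=0.3672  binned(m=10)=0.6555
```

Reading it: on the lattice the mean-field estimate is pinned at
ln 2 = 0.6931 while Kikuchi and the conditional estimate both land within
0.001–0.002 of the exact Onsager value 0.5434.  For particles, both
estimators agree in the fully mixed (≈ ln 2) and fully demixed (≈ 0)
limits — but on the clustered configuration, whose small single-type
domains sit well below the subregion size, the binned estimate still
reports near-maximal disorder (0.6555) while the conditional entropy
(0.3672) sees the local order.

## Command line

```bash
mixentropy ising -L 64 -T 3.0 --sweeps 2000 -o ising.lat
mixentropy entropy -i ising.lat --estimator conditional
mixentropy bd -n 4096 --mode demix --steps 100000 --save-every 10000 -o demix.xyz
mixentropy entropy -i demix.xyz --estimator conditional --neigh weight:bins=32
mixentropy onsager --tmin 1 --tmax 5 --steps 9
```

Simulator subcommands write a JSON manifest of the fully resolved
parameters (including the seed) next to each output; estimator output is
TSV (time, estimator, params, value_nats, n_samples, n_states_observed,
skipped, undersampled).

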