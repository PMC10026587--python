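# pimidetect

Quantitative detection of virus-like particles on a plasmonic split-ring
nanocavity array from polarization-modulated microscope image stacks.

Single viruses (tens of nanometres, low refractive index) are invisible to a
conventional bright-field microscope. One route around this is to let the
particles anchor at the gaps of gold split-ring nanocavities arranged on a
regular lattice: a bound particle breaks the ring's structural symmetry, and
the broken symmetry shows up in the *far field* as an asymmetric polarization
signature that sub-wavelength-sensitive parametric imaging can pick up.
`pimidetect` implements the complete image-analysis chain for such an assay,
together with a ground-truthed synthetic-scene generator so that every stage
can be exercised and validated end to end without access to a microscope.

## Method

**Parametric imaging.** The sample is imaged under a rotating linear
polarizer, one frame per angle (ten frames at 18° steps by default). Each
pixel follows the modulation law

$$I_i = \tfrac{1}{2} I_0 \left[ 1 + \sin\delta \,\sin 2(\theta_i - \phi) \right]$$

where $I_0$ is the mean level, $\sin\delta$ the sine of the phase difference
between the two orthogonal polarization components of the reflected light,
and $\phi$ the polarization-ellipse orientation. Because the modulation is a
pure second harmonic in $\theta$, the three parameters are recovered per
pixel by closed-form harmonic regression — exact on noiseless data,
least-squares optimal otherwise.

**Background cancellation.** The $\sin\delta$ map is segmented into
1 µm × 1 µm *topological units* centred on the lattice sites (the lattice is
registered automatically from the image's autocorrelation and symmetry, or
supplied explicitly). Every unit then has the pixelwise mean of its eight
neighbouring units subtracted:

$$L(i,j) = U(i,j) - \tfrac{1}{8} \sum_{\text{8 neighbours}} U$$

This *extended Laplace operator* cancels the repeating ring pattern and any
background varying affinely with lattice index.

**Asymmetry statistic and call rule.** A virus at one longitudinal gap
weakens that side's dipole lobe and lowers the unit's floor. Splitting a
unit patch at the transverse midline into half-sums $A$ (upper) and $B$
(lower), each unit is scored

$$\mathrm{As}_{\sin\delta} = I_{\mathrm{sum}} \cdot \left( A/B + B/A - 2 \right)$$

with $I_\mathrm{sum}$ the sum of the patch's positive pixels. A
mirror-symmetric unit scores exactly 0; $|\mathrm{As}| > 7$ calls a virus,
and the weaker half gives the attachment side (reported as a signed
directional score, + top / − bottom).

**Detection limit.** A particle landing within a capture radius
$R_\mathrm{det}$ of a ring is drawn onto a gap during droplet evaporation,
so a single particle is captured with probability
$P_1 = \pi R_\mathrm{det}^2 / L^2$ on a lattice of pitch $L$, and still
missed with probability $P_2$. For $N$ independent particles,
$P_N = 1 - (1 - P_1(1-P_2))^N$; the detection limit is the smallest $N$ with
$P_N$ above the target confidence. At the reference operating point
($R_\mathrm{det} = 210$ nm, $L = 1$ µm, $P_2 = 1/6$, target 0.999) this
gives **56 particles** per the 150 µL reference volume.

## Worked example

`examples/simulate_and_detect.py` plants six viruses on a 10 × 10 array,
renders the noisy ten-angle stack, and runs the full chain:

```
valid interior units: 64   called: 6
sensitivity: 1.000   specificity: 1.000
empirical misdetection fraction (P2 estimate): 0.000

 i  j     score  signed_score direction
 2  3 24.142663     24.142663       top
 3  8 22.307627    -22.307627    bottom
 4  6 22.393193    -22.393193    bottom
 5  2 23.581947     23.581947       top
 6  7 22.262724    -22.262724    bottom
 7  4 22.395622     22.395622       top
```

All six planted units are called (scores ≈ 22–24 against a clean-unit
envelope of ≈ 0.001 and the threshold of 7), with the correct attachment
side in every case. The other examples demodulate a single modulation
series (`demodulation_roundtrip.py`) and evaluate the detection-limit model
(`detection_limit.py`).

The same pipeline is scriptable from the shell:

```sh
pimidetect run-all --seed 1 --out out/
pimidetect lod --r-det-nm 210 --pitch-nm 1000 --p-mis 0.1667
```

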