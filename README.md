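# cervifem

Static finite-element comparison of three anterior cervical surgical
constructs on an idealized voxel model of the C4–C6 segment.

## The problem

When a focal ossification sits behind the middle of a vertebral body, a
surgeon can reach it three ways from the front: a standard anterior cervical
discectomy and fusion (**ACDF**: remove the disc, insert a PEEK interbody
cage, plate across two levels), a corpectomy (**ACCF**: remove both discs and
a central strip of the vertebral body, bridge the defect with a hollow
titanium mesh cylinder and a three-level plate), or a **modified ACDF**: a
standard ACDF plus a small rectangular osteotomy of the superior, posterior
vertebral body that opens a corridor to the ossified mass while sparing most
of the bone. The mechanical question is how each construct redistributes
axial load onto the remaining vertebral surface — the driver of implant
subsidence and vertebral collapse — and how that changes as bone quality
deteriorates (WHO groups: normal bone mass **NBM**, osteopenia **OPA**
(−2.5 < T < −1.0), osteoporosis **OPS** (T ≤ −2.5)).

`cervifem` answers this with a deliberately small, fully reproducible linear
elasticity model: layered rectangular vertebrae (cortical shell, cancellous
core, bony endplates), discs (annulus + nucleus + cartilaginous endplates),
and the three constructs applied as boolean voxel edits with the implant
dimensions of a typical instrumentation set (cage 5 × 14 × 16 mm, mesh
OD 10 / ID 8 mm, plates 16 mm wide, four 4 × 14 mm screws, 15 mm corpectomy,
8 × 9 mm osteotomy notch). The caudal vertebra is fixed at its inferior
surface; 100/150/200 N axial preloads act on the superior C4 surface; bone
loss is modelled by reducing the cortical/endplate moduli to 67 % and the
cancellous modulus to 67 % (OPA) or 33 % (OPS) of normal.

## The model

Trilinear 8-node hexahedra (one per material voxel, tied interfaces) with
full 2×2×2 Gauss quadrature; isotropic Hooke's law
σ = λ tr(ε) I + 2 μ ε with λ = Eν/((1+ν)(1−2ν)), μ = E/(2(1+ν)).
Dirichlet constraints are eliminated so reactions are exact; the reduced SPD
system is solved by sparse LU. Outputs are the element-centroid Von Mises
stress √(3/2 s:s) (s the stress deviator) and the displacement magnitude on
the superior surface of the monitored vertebra (C5, or C6 after ACCF),
summarized over the 16 monitored points of maximum variation per cell.

Because the geometry is idealized, the package makes **qualitative** claims
only — orderings across constructs, bone qualities, and loads. Absolute
stress/displacement magnitudes from any subject-specific CT geometry are
out of scope (see `docs/methods.md`).

## Worked example

```sh
$ cervifem run-case --surgery mod-acdf --bone nbm --load 100 --out demo
MOD_ACDF NBM 100 N: stress 1.86 +/- 0.57 MPa, displacement 2.95 +/- 0.13 um -> demo
```

The mean ± SD are taken over the 16 monitored surface points. The stress
table written to `demo/points_stress.csv` starts

```
point_id,element_id,x,y,z,von_mises
1,3983,7.5,1.5,11.5,2.877045129860075
2,3984,16.5,1.5,11.5,2.877045129859134
```

— the two hottest elements sit at (x ≈ 7.5, 16.5 mm, y = 1.5 mm), i.e. at
the two posterior corners of the 8 × 9 mm osteotomy notch (notch edges at
x = 8 and 16 mm, posterior margin y = 0): the partial osteotomy concentrates
load at the notch corners, exactly the subsidence-relevant feature the
modified construct introduces. Running the same case for the other two
surgeries gives mean displacements 2.14 µm (ACDF) < 2.95 µm (Mod ACDF) <
6.51 µm (ACCF): the modified construct is mechanically intermediate, and the
ordering holds in every bone-quality × load cell of the grid
(`cervifem run-grid`).

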