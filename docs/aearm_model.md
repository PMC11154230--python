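# The abridged extrinsic apoptosis reaction model (aEARM)

`fluxmodes.make_aearm()` builds a coarse-grained, mass-action ODE model of
TRAIL-induced (type-II) apoptosis execution: 22 molecular species and
28 kinetic parameters.  Every catalytic step is an explicit
enzyme–substrate–complex motif

```
E + S  <->  E:S  -->  E + P        (kf, kr, kcat)
```

so that the dominance analysis sees each binding, unbinding, and catalysis
flux separately.  Amounts are copies per cell; rate constants are s⁻¹
(first order) or s⁻¹·molecule⁻¹ (second order).

## Species (22)

| name | initial | role |
|---|---|---|
| L | 3,000 | TRAIL ligand |
| R | 200 | death receptor |
| L_R | 0 | ligand–receptor complex |
| DISC | 0 | death-inducing signaling complex |
| iC | 20,000 | initiator caspase (pro-form) |
| DISC_iC | 0 | DISC·iC complex |
| iCa | 0 | active initiator caspase |
| eCa_iC | 0 | eCa·iC feedback complex |
| Bid | 40,000 | Bid |
| iCa_Bid | 0 | iCa·Bid complex |
| tBid | 0 | truncated Bid |
| MOMP | 100,000 | MOMP precursor (Bax/Bak-like pool) |
| tBid_MOMP | 0 | tBid·MOMP complex |
| MOMPa | 0 | active MOMP signal |
| MOMPa_MOMP | 0 | feedback complex |
| eC | 10,000 | effector caspase (pro-form) |
| iCa_eC | 0 | iCa·eC complex |
| eCa | 0 | active effector caspase |
| MOMPa_eC | 0 | MOMPa·eC complex |
| PARP | 1,000,000 | PARP |
| eCa_PARP | 0 | eCa·PARP complex |
| cPARP | 0 | cleaved PARP (completion marker) |

## Reactions (19 reactions, 28 rate parameters)

1. `trail_bind`: L + R ⇌ L_R (kf_trail, kr_trail)
2. `disc_form`: L_R → DISC (kc_disc)
3. `disc_ic_*`: DISC + iC ⇌ DISC_iC → DISC + iCa (kf/kr/kc_disc_ic)
4. `ec_ic_fb_*`: eCa + iC ⇌ eCa_iC → eCa + iCa (kf/kr/kc_ec_ic_fb) — effector-caspase feedback activation of the initiator caspase
5. `ic_bid_*`: iCa + Bid ⇌ iCa_Bid → iCa + tBid (kf/kr/kc_ic_bid)
6. `bid_momp_*`: tBid + MOMP ⇌ tBid_MOMP → tBid + MOMPa (kf/kr/kc_bid_momp)
7. `momp_fb_*`: MOMPa + MOMP ⇌ MOMPa_MOMP → 2·MOMPa (kf/kr/kc_momp_fb) — self-amplifying positive feedback producing the snap-action pulse
8. `momp_deact`: MOMPa → MOMP (k_momp_deact) — first-order deactivation closing the pulse
9. `ic_ec_*`: iCa + eC ⇌ iCa_eC → iCa + eCa (kf/kr/kc_ic_ec) — type-1 activation
10. `momp_ec_*`: MOMPa + eC ⇌ MOMPa_eC → MOMPa + eCa (kf/kr/kc_momp_ec) — type-2 activation
11. `ec_parp_*`: eCa + PARP ⇌ eCa_PARP → eCa + cPARP (kf/kr/kc_ec_parp)

That is 9 catalysis blocks × 3 parameters + kf/kr for ligand binding +
kc_disc + k_momp_deact = 28 parameters.

## Nominal rates

`aearm_nominal_params()` uses the biologically plausible prior centers
1e-6 s⁻¹·molecule⁻¹ for binding, 1e-3 s⁻¹ for unbinding (and the MOMPa
deactivation), and 1 s⁻¹ for catalysis.  Under these rates cleaved PARP
rises monotonically to consume essentially the whole PARP pool.
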