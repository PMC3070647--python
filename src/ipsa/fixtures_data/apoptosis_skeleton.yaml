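# Fas-induced apoptosis network of Jurkat T cells: reaction SCHEMA only.
# All rate constants are null (to be transcribed from a published parameter
# table and supplied to ipsa.fixtures.load_apoptosis_model); initial
# concentrations default to zero and must likewise be supplied (FasL acts as
# the stimulus through its initial condition).
# Structure: receptor module (r1-r4), type-I direct cleavage of procaspase-3
# by caspase-8 (r5), Bid/Bax mitochondrial module (r6-r10), apoptosome and
# caspase-9 (r11-r13), and type-II mitochondria-dependent activation of
# caspase-3 (r14).  Naming: <rid>_f / <rid>_r forward/backward constants of
# reversible steps, <rid>_k catalytic constants of irreversible steps.
name: fas_apoptosis
states:
  [FasL, Fas, FasC, FADD, DISC, pC8, DISCpC8, C8, pC3, C3,
   Bid, tBid, Bax, tBidBax, BaxA, CytCm, PoreC, CytC,
   Apaf, Apop, pC9, ApopC9, C9]
parameters:
  r1_f: null
  r1_r: null
  r2_f: null
  r2_r: null
  r3_f: null
  r3_r: null
  r4_k: null
  r5_k: null
  r6_k: null
  r7_f: null
  r7_r: null
  r8_k: null
  r9_f: null
  r9_r: null
  r10_k: null
  r11_f: null
  r11_r: null
  r12_f: null
  r12_r: null
  r13_k: null
  r14_k: null
reactions:
  - id: r1        # FasL + Fas <-> FasC
    rate: r1_f*FasL*Fas - r1_r*FasC
    stoichiometry: {FasL: -1, Fas: -1, FasC: 1}
  - id: r2        # FasC + FADD <-> DISC
    rate: r2_f*FasC*FADD - r2_r*DISC
    stoichiometry: {FasC: -1, FADD: -1, DISC: 1}
  - id: r3        # DISC + procaspase-8 <-> DISC:pC8
    rate: r3_f*DISC*pC8 - r3_r*DISCpC8
    stoichiometry: {DISC: -1, pC8: -1, DISCpC8: 1}
  - id: r4        # DISC:pC8 -> DISC + caspase-8
    rate: r4_k*DISCpC8
    stoichiometry: {DISCpC8: -1, DISC: 1, C8: 1}
  - id: r5        # type I: caspase-8 cleaves procaspase-3
    rate: r5_k*C8*pC3
    stoichiometry: {pC3: -1, C3: 1}
  - id: r6        # caspase-8 cleaves Bid -> tBid
    rate: r6_k*C8*Bid
    stoichiometry: {Bid: -1, tBid: 1}
  - id: r7        # tBid + Bax <-> tBid:Bax
    rate: r7_f*tBid*Bax - r7_r*tBidBax
    stoichiometry: {tBid: -1, Bax: -1, tBidBax: 1}
  - id: r8        # tBid:Bax -> tBid + activated Bax
    rate: r8_k*tBidBax
    stoichiometry: {tBidBax: -1, tBid: 1, BaxA: 1}
  - id: r9        # activated Bax + mitochondrial cytochrome c <-> pore complex
    rate: r9_f*BaxA*CytCm - r9_r*PoreC
    stoichiometry: {BaxA: -1, CytCm: -1, PoreC: 1}
  - id: r10       # pore complex -> cytochrome c release
    rate: r10_k*PoreC
    stoichiometry: {PoreC: -1, BaxA: 1, CytC: 1}
  - id: r11       # CytC + Apaf <-> apoptosome
    rate: r11_f*CytC*Apaf - r11_r*Apop
    stoichiometry: {CytC: -1, Apaf: -1, Apop: 1}
  - id: r12       # apoptosome + procaspase-9 <-> complex
    rate: r12_f*Apop*pC9 - r12_r*ApopC9
    stoichiometry: {Apop: -1, pC9: -1, ApopC9: 1}
  - id: r13       # complex -> apoptosome + caspase-9
    rate: r13_k*ApopC9
    stoichiometry: {ApopC9: -1, Apop: 1, C9: 1}
  - id: r14       # type II: caspase-9 cleaves procaspase-3
    rate: r14_k*C9*pC3
    stoichiometry: {pC3: -1, C3: 1}
initial_conditions: {}
simulation: {t_start: 0.0, t_end: 10000.0, n_points: 501, rtol: 1.0e-8, atol: 1.0e-12, method: LSODA}
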