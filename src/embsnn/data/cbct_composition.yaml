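# Region composition of the 1x1 mm^2 multi-region rodent brain model
# (cortex M1/S1, thalamus VL/VM, basal ganglia, two cerebellar modules).
#
# Regional neuron totals, layer counts and type counts reproduce the
# published summary table of the model exactly (M1 58,805; S1 94,396;
# VL 6,144; VM 6,144; BG 10,976; CB 414,720 per module; total 1,005,905).
# The split of each regional total over layers and cell types is NOT
# published at this granularity; the rows below are this package's own
# composition, constrained to (a) reproduce every regional total exactly,
# (b) keep excitatory:inhibitory = 4:1 in every cortical layer except L1,
# (c) follow the published per-layer cell-type lists (SBC/ENGC in L1;
# IT/PV/SST/VIP; PT in L5B; CT in L6; 1024 TC + 1024 IN + 1024 RT per
# thalamic zone; granule-dominated cerebellum with an 8-sheet granular
# layer and 4-sheet upper molecular layer).
#
# Fields: region, layer, type, count (at scale 1), ei (E excitatory /
# I inhibitory), sheets (parallel 2D sheets the population is split over),
# interface (true for relay/input layers excluded from the type census).

regions:
  M1: {layers: 5, types: 19}
  S1: {layers: 7, types: 22}
  VL: {layers: 2, types: 3}
  VM: {layers: 2, types: 3}
  BG: {layers: 5, types: 5}
  CB_M1: {layers: 6, types: 6}
  CB_S1: {layers: 6, types: 6}

populations:
  # --- primary motor cortex (no L4) -----------------------------------
  - {region: M1, layer: L1,   type: SBC,  count: 705,   ei: I}
  - {region: M1, layer: L1,   type: ENGC, count: 1100,  ei: I}
  - {region: M1, layer: L2/3, type: IT,   count: 14400, ei: E}
  - {region: M1, layer: L2/3, type: PV,   count: 1800,  ei: I}
  - {region: M1, layer: L2/3, type: SST,  count: 1200,  ei: I}
  - {region: M1, layer: L2/3, type: VIP,  count: 600,   ei: I}
  - {region: M1, layer: L5A,  type: IT,   count: 9600,  ei: E}
  - {region: M1, layer: L5A,  type: PV,   count: 1200,  ei: I}
  - {region: M1, layer: L5A,  type: SST,  count: 800,   ei: I}
  - {region: M1, layer: L5A,  type: VIP,  count: 400,   ei: I}
  - {region: M1, layer: L5B,  type: IT,   count: 7000,  ei: E}
  - {region: M1, layer: L5B,  type: PT,   count: 5000,  ei: E}
  - {region: M1, layer: L5B,  type: PV,   count: 1800,  ei: I}
  - {region: M1, layer: L5B,  type: SST,  count: 1200,  ei: I}
  - {region: M1, layer: L6,   type: IT,   count: 5600,  ei: E}
  - {region: M1, layer: L6,   type: CT,   count: 4000,  ei: E}
  - {region: M1, layer: L6,   type: PV,   count: 1200,  ei: I}
  - {region: M1, layer: L6,   type: SST,  count: 800,   ei: I}
  - {region: M1, layer: L6,   type: VIP,  count: 400,   ei: I}

  # --- primary somatosensory cortex (L4 plus inherited additional L4) --
  - {region: S1, layer: L1,    type: SBC,  count: 1000,  ei: I}
  - {region: S1, layer: L1,    type: ENGC, count: 1396,  ei: I}
  - {region: S1, layer: L2/3,  type: IT,   count: 20800, ei: E}
  - {region: S1, layer: L2/3,  type: PV,   count: 2600,  ei: I}
  - {region: S1, layer: L2/3,  type: SST,  count: 1560,  ei: I}
  - {region: S1, layer: L2/3,  type: VIP,  count: 1040,  ei: I}
  - {region: S1, layer: L4,    type: IT,   count: 14400, ei: E}
  - {region: S1, layer: L4,    type: PV,   count: 2160,  ei: I}
  - {region: S1, layer: L4,    type: SST,  count: 1440,  ei: I}
  # additional L4 neurons, composition inherited from the published S1 model
  - {region: S1, layer: L4add, type: SSC,  count: 4800,  ei: E}
  - {region: S1, layer: L4add, type: PV,   count: 720,   ei: I}
  - {region: S1, layer: L4add, type: SST,  count: 480,   ei: I}
  - {region: S1, layer: L5A,   type: IT,   count: 11200, ei: E}
  - {region: S1, layer: L5A,   type: PV,   count: 1680,  ei: I}
  - {region: S1, layer: L5A,   type: SST,  count: 1120,  ei: I}
  - {region: S1, layer: L5B,   type: IT,   count: 9600,  ei: E}
  - {region: S1, layer: L5B,   type: PT,   count: 3200,  ei: E}
  - {region: S1, layer: L5B,   type: PV,   count: 1920,  ei: I}
  - {region: S1, layer: L5B,   type: SST,  count: 1280,  ei: I}
  - {region: S1, layer: L6,    type: IT,   count: 5600,  ei: E}
  - {region: S1, layer: L6,    type: CT,   count: 4000,  ei: E}
  - {region: S1, layer: L6,    type: PV,   count: 2400,  ei: I}

  # --- thalamus: two nuclei, each with a cerebellum-recipient and a
  # basal-ganglia-recipient zone of 1024 TC + 1024 IN + 1024 RT ---------
  - {region: VL, layer: zoneCB, type: TC, count: 1024, ei: E}
  - {region: VL, layer: zoneCB, type: IN, count: 1024, ei: I}
  - {region: VL, layer: zoneCB, type: RT, count: 1024, ei: I}
  - {region: VL, layer: zoneBG, type: TC, count: 1024, ei: E}
  - {region: VL, layer: zoneBG, type: IN, count: 1024, ei: I}
  - {region: VL, layer: zoneBG, type: RT, count: 1024, ei: I}
  - {region: VM, layer: zoneCB, type: TC, count: 1024, ei: E}
  - {region: VM, layer: zoneCB, type: IN, count: 1024, ei: I}
  - {region: VM, layer: zoneCB, type: RT, count: 1024, ei: I}
  - {region: VM, layer: zoneBG, type: TC, count: 1024, ei: E}
  - {region: VM, layer: zoneBG, type: IN, count: 1024, ei: I}
  - {region: VM, layer: zoneBG, type: RT, count: 1024, ei: I}

  # --- basal ganglia ----------------------------------------------------
  - {region: BG, layer: StriatumMSN, type: MSN,     count: 9800, ei: I}
  - {region: BG, layer: StriatumFSI, type: FSI,     count: 392,  ei: I}
  - {region: BG, layer: GPe,         type: GPe,     count: 332,  ei: I}
  - {region: BG, layer: GPiSNr,      type: GPi_SNr, count: 198,  ei: I}
  - {region: BG, layer: STN,         type: STN,     count: 254,  ei: E}

  # --- cerebellar modules (one per cortical area) -----------------------
  - {region: CB_M1, layer: mol_upper, type: stellate, count: 8192,   ei: I, sheets: 4}
  - {region: CB_M1, layer: mol_lower, type: basket,   count: 2048,   ei: I}
  - {region: CB_M1, layer: purkinje,  type: PC,       count: 1024,   ei: I}
  - {region: CB_M1, layer: granular,  type: granule,  count: 393216, ei: E, sheets: 8}
  - {region: CB_M1, layer: granular,  type: golgi,    count: 1024,   ei: I}
  - {region: CB_M1, layer: dcn,       type: DCN,      count: 1024,   ei: E}
  # Pons / mossy fibers: input layer calibrated to 8 Hz at rest
  - {region: CB_M1, layer: pons, type: MF, count: 8192, ei: E, interface: true}

  - {region: CB_S1, layer: mol_upper, type: stellate, count: 8192,   ei: I, sheets: 4}
  - {region: CB_S1, layer: mol_lower, type: basket,   count: 2048,   ei: I}
  - {region: CB_S1, layer: purkinje,  type: PC,       count: 1024,   ei: I}
  - {region: CB_S1, layer: granular,  type: granule,  count: 393216, ei: E, sheets: 8}
  - {region: CB_S1, layer: granular,  type: golgi,    count: 1024,   ei: I}
  - {region: CB_S1, layer: dcn,       type: DCN,      count: 1024,   ei: E}
  - {region: CB_S1, layer: pons, type: MF, count: 8192, ei: E, interface: true}
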