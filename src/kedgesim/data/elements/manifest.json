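{
 "energy_range_keV": [
  4.0,
  300.0
 ],
 "elements": {
  "H": {
   "Z": 1,
   "atomic_mass": 1.008,
   "density": null,
   "edges": {}
  },
  "Be": {
   "Z": 4,
   "atomic_mass": 9.0122,
   "density": 1.848,
   "edges": {}
  },
  "C": {
   "Z": 6,
   "atomic_mass": 12.011,
   "density": null,
   "edges": {}
  },
  "N": {
   "Z": 7,
   "atomic_mass": 14.007,
   "density": null,
   "edges": {}
  },
  "O": {
   "Z": 8,
   "atomic_mass": 15.999,
   "density": null,
   "edges": {}
  },
  "Al": {
   "Z": 13,
   "atomic_mass": 26.982,
   "density": 2.699,
   "edges": {}
  },
  "Ar": {
   "Z": 18,
   "atomic_mass": 39.948,
   "density": null,
   "edges": {}
  },
  "Cu": {
   "Z": 29,
   "atomic_mass": 63.546,
   "density": 8.96,
   "edges": {
    "K": 8.9789
   }
  },
  "I": {
   "Z": 53,
   "atomic_mass": 126.904,
   "density": 4.93,
   "edges": {
    "L3": 4.5571,
    "L2": 4.8521,
    "L1": 5.1881,
    "K": 33.1694
   }
  },
  "W": {
   "Z": 74,
   "atomic_mass": 183.84,
   "density": 19.3,
   "edges": {
    "L3": 10.2068,
    "L2": 11.544,
    "L1": 12.0998,
    "K": 69.525
   }
  },
  "Re": {
   "Z": 75,
   "atomic_mass": 186.207,
   "density": 21.02,
   "edges": {
    "L3": 10.5353,
    "L2": 11.9587,
    "L1": 12.5267,
    "K": 71.6764
   }
  }
 }
}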