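abbreviation,name,kind,units,description
MBW,Maximal braincase width,linear,mm,Between the most lateral points of the cerebrum (dorsal view)
MBL,Maximal braincase length,linear,mm,Posteriormost cerebellum to anteriormost olfactory bulbs (dorsal view)
MCL,Maximal cerebrum length,linear,mm,Between the posterior- and anteriormost points of the cerebrum (lateral view)
MBH,Maximal braincase height,linear,mm,Ventralmost medulla oblongata to dorsalmost cerebrum (lateral view)
MCH,Maximal cerebrum height,linear,mm,Between the ventral- and dorsalmost points of the cerebrum (lateral view)
OBW,Olfactory bulbs width,linear,mm,Between the lateral points of the olfactory-bulb/cerebrum contact (ventral view)
MICW,Minimal intercanal complex width,linear,mm,Between the maximal concave curvatures of the intercanal complex borders (ventral view)
MCW,Maximal cerebellum width,linear,mm,Between the most lateral points of the cerebellum (occipital view)
OBH,Olfactory bulbs height,linear,mm,Between the ventral- and dorsalmost points of the olfactory-bulb/cerebrum contact
IHA,Intersphenorbital-hypophyseal angle,angle,degrees,Deviation of the medial sphenorbital-fissure edges from the hypophyseal notch (ventral view)
HPA,Hypophyseal-pons angle,angle,degrees,Posteroventral orientation of the pons relative to the hypophyseal plane (lateral view)
CSA,Cerebellum-spinal cord angle,angle,degrees,Posterior cerebellum plane relative to the spinal-cord plane (lateral view)
OFA,Olfactory bulbs-frontal lobe angle,angle,degrees,Posterior olfactory-bulb plane relative to the anterior frontal-lobe plane (lateral view)
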