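study_id,year,first_author,species,strain,tumor,intervention,n_treat,n_ctrl,rmst_treat,se_treat,rmst_ctrl,se_ctrl,mr,se_mr,source
Han 2014,2014,Han,Humans,Humans,GBM,CR+,11,23,41.36,4.02,23.70,2.85,1.75,0.27,Figure
Rieger 2015,2015,Rieger,Humans,Humans,GBM,KD,8,5,7.25,1.07,5.16,1.29,1.41,0.41,Figure
Santos 2018,2018,Santos,Humans,Humans,GBM,KD+,17,15,10.56,0.94,8.38,1.49,1.26,0.25,Author
Zhou 2007 C57BL KD,2007,Zhou,C57BL mice,C57BL/6J,CT-2A astrocytoma (syn.),KD,9,7,19.78,0.84,17.71,0.94,1.12,0.08,Author
Zhou 2007 C57BL CR,2007,Zhou,C57BL mice,C57BL/6J,CT-2A astrocytoma (syn.),CR,11,7,31.82,2.26,17.71,0.94,1.80,0.16,Author
Zhou 2007 SCID KD,2007,Zhou,SCID mice,BALBc/J SCID,U87 glioma (xen.),KD,7,11,19.71,0.78,21.27,1.84,0.93,0.09,Author
Zhou 2007 SCID CR,2007,Zhou,SCID mice,BALBc/J SCID,U87 glioma (xen.),CR,14,11,30.36,1.40,21.27,1.84,1.43,0.14,Author
Marsh 2008,2008,Marsh,C57BL mice,C57BL/6J,CT-2A astrocytoma (syn.),CR,8,7,30.50,4.09,18.86,1.20,1.62,0.24,Figure
Stafford 2010,2010,Stafford,C57BL mice,C57BL/6J albino,GL261 glioma (syn.),KD,5,5,24.00,0.94,19.00,0.63,1.26,0.06,Author
Maurer 2011,2011,Maurer,Athymic mice,Athymic,LNT-229 glioma (xen.),KD,12,12,87.83,4.59,96.90,3.57,0.91,0.06,Author
Abdelwahab 2012 KD,2012,Abdelwahab,C57BL mice,C57BL/6J albino,GL261 glioma (syn.),KD,20,19,33.90,5.12,23.32,1.08,1.45,0.23,Author
Abdelwahab 2012 KD+,2012,Abdelwahab,C57BL mice,C57BL/6J albino,GL261 glioma (syn.),KD+,11,11,97.36,4.93,54.73,9.81,1.78,0.33,Figure
Jiang 2013,2013,Jiang,Athymic mice,Athymic,U87 glioma (xen.),CR,7,7,26.71,1.55,18.71,0.85,1.43,0.11,Figure
Rieger 2014 KD,2014,Rieger,Athymic mice,Athymic,U87 glioma (xen.),KD,8,8,35.62,0.64,33.88,1.53,1.05,0.05,Author
Rieger 2014 KD+,2014,Rieger,Athymic mice,Athymic,U87 glioma (xen.),KD+,8,8,57.50,2.28,50.25,2.24,1.14,0.07,Figure
Martuscello 2015 L0,2015,Martuscello,SCID mice,NOD/SCID,L0 glioma (xen.),KD,10,11,48.50,5.63,14.55,1.57,3.33,0.53,Figure
Martuscello 2015 L2,2015,Martuscello,SCID mice,NOD/SCID,L2 glioma (xen.),KD,5,6,55.20,8.15,25.50,2.38,2.17,0.38,Figure
De Feyter 2016 9L,2016,De Feyter,Fisher rats,Fisher rats,9L glioma (xen.),KD,10,9,34.70,1.63,32.56,1.33,1.07,0.07,Author
De Feyter 2016 RG2,2016,De Feyter,Fisher rats,Fisher rats,RG2 glioma (xen.),KD,10,11,26.30,1.11,27.36,0.71,0.96,0.05,Author
Lussier 2016,2016,Lussier,C57BL mice,C57BL/6J albino,GL261 glioma (syn.),KD,12,11,42.17,2.52,33.09,1.45,1.27,0.09,Figure
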